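"""The ab initio reconstruction model and its fitted results.

`AbInitioModel` bundles a particle stack, per-particle CTF metadata and the
2D-class information; `fit()` runs the eight-stage probabilistic ab initio
search (hybrid SHC + probabilistic orientation assignment, class-restrained
balanced importance sampling, frequency marching with per-stage downscaling,
ML/ICM regularization, optional multi-volume state classification) and
returns an `AbInitioResults` carrying the map(s), the particle table with
assigned orientations/states, diagnostics and a text summary.

The orientation matching itself runs in polar Fourier coordinates: the
reference volume is reprojected as polar sections over an S2 x S1 grid, and
the noise-weighted normalized Euclidean cost of every particle against
every (direction, in-plane) cell is evaluated with FFT correlations along
the angular axis. All randomness flows from one seeded generator, so runs
are bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.optimize import minimize

from . import io as pio
from .fourier import (
    DensityVolume,
    FourierVolume,
    apply_spherical_mask,
    ctf_image,
    fourier_crop_stack,
    fsc_curve,
    ft2,
    ift2,
    resample_volume,
    resolution_at_threshold,
)
from .geometry import (
    SO3Grid,
    build_so3_grid,
    matrix_to_euler_zyz,
    random_rotations,
    rot_z,
    symmetry_ops,
)
from .multistate import init_states, rescue_empty_states, split_docked
from .reconstruct import finalize_map, reconstruct_halfmaps
from .regularize import RegularizerConfig
from .schedule import (
    ClassInfo,
    MarchPlan,
    estimate_lowpass_auto,
    plan_frequency_march,
    stage_config,
)
from .search import (
    AngularThreshold,
    neighborhood_size,
    sample_inplane,
    update_angular_threshold,
)

_CHUNK = 64  # particles per matching chunk (memory/GEMM balance)


@dataclass
class AbInitioResults:
    """Fitted maps, particle assignments and run diagnostics."""

    volumes: list  # DensityVolume per state, final box
    half_maps: list  # (even, odd) per state
    fsc_curves: list  # half-map FSC per state
    particle_table: pd.DataFrame
    march_plan: MarchPlan
    eps_history: list
    cost_history: list
    lp_history: list
    state_counts: np.ndarray
    config: pio.RunConfig
    runtime_s: float
    log: list = field(default_factory=list)

    def resolution(self, state: int = 0, threshold: float = 0.143) -> float:
        v = self.volumes[state]
        return resolution_at_threshold(self.fsc_curves[state], threshold, v.box, v.pixel_size)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Probabilistic ab initio 3D reconstruction",
            "=" * 57,
            f"particles: {len(self.particle_table)}   states: {cfg.nstates}"
            f" ({cfg.het_mode})   symmetry: {cfg.symmetry}",
            f"nsample: {cfg.nsample}   seed: {cfg.seed}   runtime: {self.runtime_s:.1f} s",
            "",
            "frequency march",
            self.march_plan.describe(),
            "",
            f"final angular threshold: {self.eps_history[-1]:.2f} deg",
            f"mean cost (last iteration): {self.cost_history[-1]:.4f}",
        ]
        for k, v in enumerate(self.volumes):
            lines.append(
                f"state {k}: {int(self.state_counts[k])} particles, "
                f"half-map FSC 0.143 at {self.resolution(k):.2f} A "
                f"(box {v.box}, {v.pixel_size:.2f} A/px)"
            )
        return "\n".join(lines)

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, v in enumerate(self.volumes):
            pio.write_mrc(outdir / f"state_{k}.mrc", v)
            pio.write_mrc(outdir / f"state_{k}_even.mrc", self.half_maps[k][0])
            pio.write_mrc(outdir / f"state_{k}_odd.mrc", self.half_maps[k][1])
            np.savetxt(
                outdir / f"state_{k}_fsc.txt",
                np.column_stack([np.arange(len(self.fsc_curves[k])), self.fsc_curves[k]]),
                header="shell fsc",
            )
        pio.write_particle_table(outdir / "particles.tsv", self.particle_table)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        (outdir / "run.json").write_text(
            json.dumps(
                {
                    "eps_history": list(map(float, self.eps_history)),
                    "cost_history": list(map(float, self.cost_history)),
                    "lp_history": list(map(float, self.lp_history)),
                    "state_counts": [int(c) for c in self.state_counts],
                    "config": json.loads(self.config.to_json()),
                    "log": self.log,
                },
                indent=2,
            )
        )

    def plot_fsc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for k, c in enumerate(self.fsc_curves):
            ax.plot(np.arange(len(c)), c, label=f"state {k}")
        ax.axhline(0.143, ls="--", c="gray")
        ax.set_xlabel("shell")
        ax.set_ylabel("FSC")
        ax.legend()
        return ax

    def plot_eps(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.eps_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("angular threshold (deg)")
        return ax


class AbInitioModel:
    """Ab initio 3D reconstruction model over a particle stack."""

    def __init__(
        self,
        images: np.ndarray,
        ctf_params: list,
        classes: list[ClassInfo],
        pixel_size: float,
        config: pio.RunConfig | None = None,
    ):
        self.images = np.ascontiguousarray(images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a (N, L, L) stack")
        self.n_particles, self.box, _ = self.images.shape
        self.ctf_params = ctf_params
        self.classes = classes
        self.pixel_size = float(pixel_size)
        self.config = config or pio.RunConfig()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_simulation(cls, stack, truth, classes, pixel_size, config=None):
        return cls(stack, truth.ctf_params, classes, pixel_size, config)

    @classmethod
    def from_files(cls, stack_path, table_path, frc_path, config=None):
        from .fourier import CTFParams

        data, pixel = pio.read_mrc(stack_path)
        table = pio.read_particle_table(table_path)
        ctfs = [
            CTFParams(
                defocus_u=r.defocus_u,
                defocus_v=r.defocus_v,
                astig_angle=r.astig_angle,
                cs=r.cs,
                voltage=r.voltage,
                amp_contrast=r.amp_contrast,
            )
            for r in table.itertuples()
        ]
        frcs = pio.read_class_frcs(frc_path)
        classes = []
        for cid, frc in frcs.items():
            members = table.index[table["class_id"] == cid].to_numpy()
            scores = table.loc[members, "class_score"].to_numpy()
            classes.append(ClassInfo(cid, members, scores, frc))
        return cls(np.atleast_3d(data), ctfs, classes, pixel, config)

    # -- fitting ------------------------------------------------------------

    def fit(self, resume: bool = False, progress=None) -> AbInitioResults:
        runner = _Runner(self, resume=resume, progress=progress)
        return runner.run()


# ---------------------------------------------------------------------------
# internal stage runner
# ---------------------------------------------------------------------------


class _Runner:
    def __init__(self, model: AbInitioModel, resume=False, progress=None):
        self.m = model
        self.cfg = model.config
        self.rng = np.random.default_rng(self.cfg.seed)
        self.progress = progress or (lambda msg: None)
        self.resume = resume
        self.d_total = model.box * model.pixel_size
        self.reg_cfg = RegularizerConfig(
            tau=self.cfg.tau,
            lam=self.cfg.lam,
            levels=self.cfg.icm_levels,
            icm_sweeps=self.cfg.icm_sweeps,
        )
        self.sym_ops = symmetry_ops(self.cfg.symmetry)
        self.log = []
        # per-particle state (original-box units)
        n = model.n_particles
        self.rots = np.repeat(np.eye(3)[None], n, axis=0)
        self.shifts = np.zeros((n, 2))
        self.costs = np.full(n, np.inf)
        self.state_conf = np.ones(n)  # state-assignment confidence weights
        self.n_updates = np.zeros(n, dtype=np.int64)
        self.eps = AngularThreshold(self.cfg.initial_epsilon)
        self.eps_history = []
        self.cost_history = []
        self.lp_history = []
        self.full_fts = ft2(model.images).astype(np.complex64)
        self.march = plan_frequency_march(
            model.classes, model.box, model.pixel_size, self.cfg.final_lp
        )
        self.states = init_states(n, self.cfg.nstates, self.cfg.het_mode, self.rng)
        # docked heterogeneity refines one average volume until the final
        # stage; independent mode searches all states from the start
        self.K_active = (
            1 if (self.cfg.het_mode == "docked" and self.cfg.nstates > 1) else self.cfg.nstates
        )
        self.volumes = None  # list of DensityVolume at current stage box
        self.start_stage = 1
        self._log(f"march plan:\n{self.march.describe()}")
        self._log(
            f"defaults: tau={self.cfg.tau} lambda={self.cfg.lam} "
            f"levels={self.cfg.icm_levels} sweeps={self.cfg.icm_sweeps} "
            f"eps0={self.cfg.initial_epsilon} shift_bound={self.cfg.shift_bound} "
            f"coupling={self.cfg.coupling} "
            f"angular_oversampling={self.cfg.angular_oversampling}"
        )
        if self.cfg.stage_iter_override:
            self._log(f"user override of stage iterations: {self.cfg.stage_iter_override}")
        if resume and self.cfg.output_dir:
            self._load_checkpoint()

    def _log(self, msg):
        self.log.append(msg)
        self.progress(msg)

    # -- checkpointing ------------------------------------------------------

    def _ckpt_path(self):
        return Path(self.cfg.output_dir) / "checkpoint.npz"

    def _save_checkpoint(self, completed_stage):
        if not self.cfg.output_dir:
            return
        Path(self.cfg.output_dir).mkdir(parents=True, exist_ok=True)
        np.savez(
            self._ckpt_path(),
            stage=completed_stage,
            rots=self.rots,
            shifts=self.shifts,
            costs=self.costs,
            labels=self.states.labels,
            n_updates=self.n_updates,
            eps=self.eps.epsilon,
            eps_history=np.asarray(self.eps_history),
            cost_history=np.asarray(self.cost_history),
            lp_history=np.asarray(self.lp_history),
            volumes=np.stack([v.grid for v in self.volumes]),
            vol_pixel=self.volumes[0].pixel_size,
            rng_state=json.dumps(self.rng.bit_generator.state),
        )

    def _load_checkpoint(self):
        p = self._ckpt_path()
        if not p.exists():
            return
        z = np.load(p, allow_pickle=False)
        self.rots = z["rots"]
        self.shifts = z["shifts"]
        self.costs = z["costs"]
        self.n_updates = z["n_updates"]
        self.states.labels = z["labels"]
        self.eps = AngularThreshold(float(z["eps"]))
        self.eps_history = list(z["eps_history"])
        self.cost_history = list(z["cost_history"])
        self.lp_history = list(z["lp_history"])
        self.volumes = [
            DensityVolume(g, float(z["vol_pixel"])) for g in z["volumes"]
        ]
        self.rng.bit_generator.state = json.loads(str(z["rng_state"]))
        self.start_stage = int(z["stage"]) + 1
        self._log(f"resumed from checkpoint after stage {int(z['stage'])}")

    # -- main loop ----------------------------------------------------------

    def run(self) -> AbInitioResults:
        t0 = time.time()
        last = None
        for stage in range(self.start_stage, 9):
            try:
                last = self._run_stage(stage)
            except Exception:
                self._save_checkpoint(stage - 1)
                raise
            self._save_checkpoint(stage)
        return self._results(last, time.time() - t0)

    def _run_stage(self, stage: int):
        scfg = stage_config(stage)
        iters = self.cfg.stage_iter_override.get(stage, scfg.max_iterations)
        box = int(self.march.boxes[stage - 1])
        lp = float(self.march.lowpass[stage - 1])
        apix = self.d_total / box
        sd = _StageData(self, stage, box, apix, lp)
        self._log(
            f"stage {stage}: box {box} ({apix:.2f} A/px), lp {lp:.2f} A "
            f"(r={sd.r_lp}), {sd.grid.n_dirs} dirs x {sd.grid.n_inplane} in-plane, "
            f"{scfg.search}, reg={scfg.regularization}, iters={iters}"
        )

        if self.volumes is None:
            self._random_init(sd, scfg)
        else:
            self.volumes = [resample_volume(v, box) for v in self.volumes]
        if (
            self.states.mode == "docked"
            and self.states.n_states > 1
            and stage == 8
            and self.K_active == 1
        ):
            self.states = split_docked(self.states, self.rng)
            self.K_active = self.states.n_states
            self._log("docked mode: random state split before final stage")
            self.volumes = [self.volumes[0].copy() for _ in range(self.states.n_states)]

        recon = None
        for it in range(iters):
            # stochastic sampling drives the optimization; the closing
            # iterations of the final stage anneal to the maximum-likelihood
            # assignment (and the table reports the MAP estimate)
            final_polish = stage == 8 and it >= iters - 5
            recon = self._iterate(sd, scfg, stage, it, greedy=final_polish)
        return sd, recon

    def _random_init(self, sd: "_StageData", scfg):
        n = self.m.n_particles
        self.rots = random_rotations(n, self.rng)
        sel = self._select(scfg, sd)
        self.volumes = self._reconstruct_all(sd, sel, mode="none")[0]
        self._log("random orientation initialization")

    def _select(self, scfg, sd) -> np.ndarray:
        from .schedule import select_balanced

        nsample = min(self.cfg.nsample, self.m.n_particles)
        return np.sort(
            select_balanced(self.m.classes, nsample, scfg.selection_phase, self.rng)
        )

    # -- one optimization iteration -----------------------------------------

    def _iterate(self, sd: "_StageData", scfg, stage: int, it: int, greedy: bool = False):
        rng = self.rng
        K = self.K_active
        sel = self._select(scfg, sd)
        grid = sd.grid
        A = grid.n_inplane
        M = grid.n_dirs

        refs = [
            FourierVolume.from_density(v) for v in self.volumes
        ]
        S = np.concatenate(
            [r.extract_polar_sections(grid.dir_rots, sd.rings, A) for r in refs]
        )  # (K*M, R, A)
        FS = sfft.fft(S, axis=-1)
        FSc_t = np.ascontiguousarray(np.transpose(np.conj(FS), (2, 1, 0)))  # (A,R,KM)
        # reference power per ring, summed over angle: the in-plane variation
        # of the reference energy term comes only from CTF astigmatism and is
        # folded in via the angular mean of w * H^2
        S_pow = np.ascontiguousarray(
            np.sum(np.abs(S) ** 2, axis=-1).T.astype(np.float32)
        )  # (R, KM)
        # reference-noise compensation between states: a state rebuilt from
        # fewer particles carries a noisier reference, inflating every
        # residual against it and collapsing the labels onto the larger
        # state. The expected inflation is the reference noise power — the
        # fraction 1/(1 + SSNR) of the reference power, with SSNR from each
        # state's half-map FSC — and is subtracted from the residual.
        S_noise = None
        if (
            self.REF_NOISE_COMPENSATION
            and K > 1
            and getattr(self, "state_fsc", None)
            and len(self.state_fsc) == K
        ):
            S_noise = np.empty_like(S_pow)
            for k in range(K):
                f = np.clip(self.state_fsc[k], 0.0, 0.999)
                shells = np.clip(sd.rings.astype(int), 0, len(f) - 1)
                ssnr = 2.0 * f[shells] / (1.0 - f[shells])
                nf = (1.0 / (1.0 + ssnr)).astype(np.float32)
                S_noise[:, k * M : (k + 1) * M] = (
                    S_pow[:, k * M : (k + 1) * M] * nf[:, None]
                )

        # map previous orientations onto this grid
        prev_m, prev_a = _map_rotations(self.rots[sel], grid)
        prev_state = self.states.labels[sel]
        prev_cell = (prev_state * M + prev_m) * A + prev_a

        # particle-side quantities at the current shifts
        P = sd.polar[sel] * sd.shift_ramp(self.shifts[sel])
        H = sd.ctf_polar[sel]
        ring_w = sd.ring_counts / A
        sigma2 = self._noise_sigma2(sd, P, H, S, prev_state * M + prev_m, prev_a, it, stage)
        w = (ring_w[None] / sigma2).astype(np.float32)  # (n, R)

        Q = (P * H * w[:, :, None]).astype(np.complex64)
        E_P = np.einsum("nra->n", (w[:, :, None] * (np.abs(P) ** 2))).astype(np.float64)
        W2 = (w[:, :, None] * H * H).astype(np.float32)

        eps_eff = max(self.eps.epsilon, sd.spacing)
        n_sel = len(sel)
        probabilistic = scfg.search == "probabilistic"
        if probabilistic:
            Qh = neighborhood_size(grid, eps_eff, K)
            top_idx = np.empty((n_sel, Qh), dtype=np.int64)
            top_aff = np.empty((n_sel, Qh), dtype=np.float32)
            top_num = np.empty((n_sel, Qh), dtype=np.float64)
            state_best = np.full((n_sel, K), np.inf)
            row_sum = np.empty(n_sel)
            gmin, gmax = np.inf, -np.inf
            prev_aff = np.empty(n_sel)
        else:
            chosen = np.empty(n_sel, dtype=np.int64)
            chosen_cost = np.empty(n_sel)

        for lo in range(0, n_sel, _CHUNK):
            hi = min(lo + _CHUNK, n_sel)
            aff, den = self._match_chunk(
                Q[lo:hi], W2[lo:hi], FSc_t, S_pow, E_P[lo:hi], A, S_noise
            )  # (c, KM, A) affinity = 1 - d; den = weighted power sum
            c = hi - lo
            flat = aff.reshape(c, -1)
            if probabilistic:
                if K > 1:
                    # stratify the neighborhood across states: once epsilon
                    # has contracted, a global top-Q would only contain the
                    # better-reconstructed state's cells and labels could
                    # never flip
                    Qp = max(1, Qh // K)
                    parts = []
                    MA = M * A
                    for k in range(K):
                        blk = flat[:, k * MA : (k + 1) * MA]
                        pk = np.argpartition(-blk, Qp - 1, axis=1)[:, :Qp]
                        parts.append(pk + k * MA)
                    part = np.concatenate(parts, axis=1)[:, :Qh]
                else:
                    part = np.argpartition(-flat, Qh - 1, axis=1)[:, :Qh]
                top_idx[lo:hi] = part
                top_aff[lo:hi] = np.take_along_axis(flat, part, axis=1)
                # noise-weighted squared residual of the top cells: the
                # Gaussian log-likelihood scale of the multinomial draw
                den_top = np.take_along_axis(den, part // A, axis=1)
                top_num[lo:hi] = 2.0 * den_top * (1.0 - top_aff[lo:hi])
                if K > 1:
                    cell_state = part // (M * A)
                    for k in range(K):
                        vals = np.where(cell_state == k, top_num[lo:hi], np.inf)
                        state_best[lo:hi, k] = vals.min(axis=1)
                rs = flat.sum(axis=1, dtype=np.float64)
                row_sum[lo:hi] = rs
                # global min-max runs over the row-normalized values
                gmin = min(gmin, float((flat.min(axis=1) / rs).min()))
                gmax = max(gmax, float((flat.max(axis=1) / rs).max()))
                prev_aff[lo:hi] = flat[np.arange(c), prev_cell[lo:hi]]
            else:
                dir_costs = 1.0 - aff.max(axis=2)  # best in-plane per direction
                prev_cost_row = 1.0 - flat[np.arange(c), prev_cell[lo:hi]]
                del den
                pc = np.where(
                    np.isfinite(self.costs[sel[lo:hi]]), prev_cost_row, np.inf
                )
                from .search import shc_pick_batch

                picks = shc_pick_batch(dir_costs, pc, rng)
                for j in range(c):
                    mtot = picks[j]
                    a_idx = sample_inplane(1.0 - aff[j, mtot], eps_eff, rng)
                    chosen[lo + j] = mtot * A + a_idx
                    chosen_cost[lo + j] = 1.0 - aff[j, mtot, a_idx]

        if probabilistic:
            if greedy:
                # MAP report: minimize the noise-weighted squared residual
                # (the likelihood the sampler concentrates on), not the
                # size-normalized affinity
                best = np.argmin(top_num, axis=1)
                chosen = top_idx[np.arange(n_sel), best]
                chosen_cost = 1.0 - top_aff[np.arange(n_sel), best].astype(np.float64)
            else:
                chosen, chosen_cost = self._sequential_sample(
                    sd, grid, K, top_idx, top_aff, top_num, row_sum, gmin, gmax, rng, sel
                )

        # decode cells, update per-particle state
        chosen_cost = np.clip(chosen_cost, 0.0, 1.0)
        mtot, a_idx = np.divmod(chosen, A)
        state_new, m_new = np.divmod(mtot, M)
        if probabilistic and K > 1:
            self._last_state_best = state_best
            self._last_sel = sel
            # state-assignment confidence from the posterior odds of the
            # best cell per state; used to down-weight uncertain particles
            # in the per-state reconstructions
            own = state_best[np.arange(n_sel), state_new]
            other = np.where(
                np.arange(K)[None, :] == state_new[:, None], np.inf, state_best
            ).min(axis=1)
            delta = np.clip(other - own, -60.0, 60.0)
            self.state_conf[sel] = np.clip(1.0 / (1.0 + np.exp(-0.5 * delta)), 0.05, 1.0)
        old_dirs = self.rots[sel][:, :, 2].copy()
        new_rots = np.einsum(
            "nij,njk->nik",
            grid.dir_rots[m_new],
            _rotz_batch(-np.deg2rad(grid.inplane_deg[a_idx])),
        )
        self.rots[sel] = new_rots
        self.states.labels[sel] = state_new
        self.costs[sel] = chosen_cost
        self.n_updates[sel] += 1

        # trial-shift rescue for poorly matching particles: a particle whose
        # stored shift is far off cannot rank its true direction, deadlocking
        # orientation and shift; re-matching its row over a small grid of
        # candidate shifts breaks the deadlock
        rescue_now = scfg.shift_search and self.cfg.shift_bound > 0 and (
            sd.box < self.m.box or it % 3 == 0
        )
        if rescue_now:
            resc = np.flatnonzero(
                chosen_cost > np.quantile(chosen_cost, 0.85)
            )
            if len(resc):
                self._trial_shift_rescue(
                    sd, grid, K, sel, resc, FSc_t, S_pow, w, chosen, chosen_cost, S_noise
                )
                mtot, a_idx = np.divmod(chosen, A)
                state_new, m_new = np.divmod(mtot, M)
                new_rots = np.einsum(
                    "nij,njk->nik",
                    grid.dir_rots[m_new],
                    _rotz_batch(-np.deg2rad(grid.inplane_deg[a_idx])),
                )
                self.rots[sel] = new_rots
                self.states.labels[sel] = state_new
                self.costs[sel] = chosen_cost

        # continuous shift refinement at the assigned orientation (the damped
        # updates settle over a few iterations; in the two expensive final
        # stages every other iteration is plenty)
        refine_now = scfg.shift_search and self.cfg.shift_bound > 0 and (
            stage < 7 or it % 2 == 0 or greedy
        )
        if refine_now:
            self._refine_shifts(sd, refs, sel, new_rots, state_new, w)

        # adaptive angular threshold from the S2 geodesic changes
        changes = np.rad2deg(
            np.arccos(np.clip(np.sum(old_dirs * new_rots[:, :, 2], axis=1), -1, 1))
        )
        self.eps = update_angular_threshold(changes, AngularThreshold(eps_eff), sd.spacing)
        self.eps_history.append(self.eps.epsilon)
        self.cost_history.append(float(np.mean(chosen_cost)))

        # reconstruction and regularization -> new reference volume(s)
        self.volumes, recon = self._reconstruct_all(
            sd, sel, mode=scfg.regularization
        )

        # automatic low-pass estimation in the last two stages
        if stage >= 7:
            main = int(np.argmax(self.states.counts()))
            auto = estimate_lowpass_auto(
                recon[main].even_map,
                recon[main].odd_map,
                0.5 * self.cfg.mask_diameter_frac * sd.box,
                previous=self.d_total / sd.r_lp,
            )
            # the data-driven limit may move anywhere between the planned
            # final limit and the mid-schedule limit: trust the even/odd
            # estimate rather than the class-FRC plan
            lp_dyn = float(
                np.clip(auto, self.march.lowpass[7], self.march.lowpass[4])
            )
            sd.set_lowpass(lp_dyn)
        self.lp_history.append(self.d_total / sd.r_lp)
        return recon

    def _match_chunk(self, Q, W2, FSc_t, S_pow, E_P, A, S_noise=None):
        """Affinity (chunk, K*M, A) and weighted power sums, FFT over angle."""
        FQ_t = np.ascontiguousarray(np.transpose(sfft.fft(Q, axis=-1), (2, 0, 1)))
        G = FQ_t @ FSc_t  # (A, c, KM)
        C = sfft.ifft(G, axis=0, overwrite_x=True).real  # float32
        Wm = W2.mean(axis=2)
        E_S = Wm @ S_pow  # (c, KM): angle-mean weighting
        den = np.maximum(E_P[:, None] + E_S, 1e-30)
        den32 = den.astype(np.float32)
        aff = np.float32(0.5) + C.transpose(1, 2, 0) / den32[:, :, None]
        if S_noise is not None:
            # subtract the expected reference-noise residual (see _iterate)
            aff += ((Wm @ S_noise) / (2.0 * den)).astype(np.float32)[:, :, None]
        return aff, den

    REF_NOISE_COMPENSATION = True

    # Relative floor on the per-ring noise power: sigma2 estimated at a
    # not-yet-converged orientation can collapse on accidental matches and
    # let single rings dominate the weighting; flooring at a fraction of the
    # ring power bounds any ring's weight without touching the noise-
    # dominated regime (residual ~ ring power at realistic SNR).
    SIGMA2_REL_FLOOR = 0.05

    def _noise_sigma2(self, sd, P, H, S, prev_km, prev_a, it, stage):
        """Per-ring noise power at the previous best orientation.

        With several states the residual is taken against the state-averaged
        reference section: estimating it against the particle's currently
        assigned state would inflate sigma2 exactly on the rings that
        discriminate the states for mislabeled particles, locking them in.
        """
        n, R, A = P.shape
        power = np.mean(np.abs(P) ** 2, axis=2)
        if stage == 1 and it == 0:
            return np.maximum(power, 1e-12 * max(power.mean(), 1e-30))
        K = self.K_active
        M = len(S) // K
        j = (np.arange(A)[None, None, :] - prev_a[:, None, None]) % A
        prev_m = prev_km % M
        if K > 1:
            ref = np.mean(
                [np.take_along_axis(S[k * M + prev_m], j, axis=2) for k in range(K)],
                axis=0,
            )
        else:
            ref = np.take_along_axis(S[prev_m], j, axis=2)
        resid = np.abs(P - H * ref) ** 2
        sigma2 = resid.mean(axis=2)
        return np.maximum(sigma2, self.SIGMA2_REL_FLOOR * power)

    def _sequential_sample(
        self, sd, grid, K, top_idx, top_aff, top_num, row_sum, gmin, gmax, rng, sel
    ):
        """Sequentially coupled multinomial sampling over the neighborhoods.

        The draw combines the min-max-normalized table probability with the
        Gaussian likelihood implied by the noise-weighted residual,
        exp(-(num - num_min)/2); the likelihood factor concentrates the
        multinomial on statistically plausible cells while the table and
        occupancy damping carry the particle-to-particle coupling.
        """
        A = grid.n_inplane
        M = grid.n_dirs
        span = max(gmax - gmin, 1e-30)
        n_sel = len(sel)
        occupancy = np.zeros(K * M)
        expected = max(n_sel / (K * M), 1e-9)
        chosen = np.empty(n_sel, dtype=np.int64)
        chosen_cost = np.empty(n_sel)
        order = rng.permutation(n_sel)
        coupling = self.cfg.coupling
        for p in order:
            cells = top_idx[p]
            probs = (top_aff[p] / row_sum[p] - gmin) / span
            probs = np.maximum(probs, 1e-12)
            like = np.exp(-0.5 * np.minimum(top_num[p] - top_num[p].min(), 1400.0))
            probs = probs * like
            if coupling:
                dirs = cells // A
                probs = probs / (1.0 + occupancy[dirs] / expected)
            tot = probs.sum()
            if tot <= 0 or not np.isfinite(tot):
                pick = int(cells[np.argmax(top_aff[p])])
            else:
                u = rng.random() * tot
                pick = int(cells[np.searchsorted(np.cumsum(probs), u)])
            chosen[p] = pick
            occupancy[pick // A] += 1.0
            chosen_cost[p] = 1.0 - _affinity_of(top_idx[p], top_aff[p], pick)
        return chosen, chosen_cost

    def _trial_shift_rescue(
        self, sd, grid, K, sel, resc, FSc_t, S_pow, w, chosen, chosen_cost, S_noise=None
    ):
        """Joint (orientation, shift) re-search over a coarse shift grid.

        For the rescued particles the polar matching row is recomputed at a
        small set of absolute candidate shifts (current value, the origin
        and two rings of the shift box); the globally best (cell, shift)
        replaces the assignment when it improves the cost. Greedy by design:
        this is a repair step, not the regular sampler.
        """
        A = grid.n_inplane
        scale = sd.box / self.m.box
        bound = self.cfg.shift_bound * scale
        trials = [np.zeros(2)]
        for frac, off in ((1 / 3, 0.0), (2 / 3, np.pi / 4)):
            for q in range(4):
                th = np.pi / 2 * q + off
                trials.append(bound * frac * np.array([np.cos(th), np.sin(th)]))
        idx = sel[resc]
        n_r = len(resc)
        cur = self.shifts[idx] * scale
        cand = np.concatenate(
            [cur[:, None, :], np.broadcast_to(np.stack(trials), (n_r, len(trials), 2))],
            axis=1,
        )  # (n_r, T, 2) absolute stage-pixel shifts
        T = cand.shape[1]
        c = 2.0 * np.pi / sd.box
        ramp = np.exp(
            1j
            * c
            * (
                sd.ring_x[None, None] * cand[..., 0, None, None]
                + sd.ring_y[None, None] * cand[..., 1, None, None]
            )
        ).astype(np.complex64)
        P_t = (sd.polar[idx][:, None] * ramp).reshape(n_r * T, *sd.polar.shape[1:])
        H_t = np.broadcast_to(
            sd.ctf_polar[idx][:, None], (n_r, T) + sd.ctf_polar.shape[1:]
        ).reshape(P_t.shape)
        w_t = np.broadcast_to(w[resc][:, None], (n_r, T, w.shape[1])).reshape(
            n_r * T, w.shape[1]
        )
        Q_t = (P_t * H_t * w_t[:, :, None]).astype(np.complex64)
        E_Pt = np.einsum("nra->n", w_t[:, :, None] * np.abs(P_t) ** 2)
        W2_t = (w_t[:, :, None] * H_t * H_t).astype(np.float32)
        best_cost = np.full(n_r, np.inf)
        best_cell = np.zeros(n_r, dtype=np.int64)
        best_trial = np.zeros(n_r, dtype=np.int64)
        MA = grid.size
        cur_state = self.states.labels[idx]
        for lo in range(0, n_r * T, _CHUNK):
            hi = min(lo + _CHUNK, n_r * T)
            aff, _ = self._match_chunk(
                Q_t[lo:hi], W2_t[lo:hi], FSc_t, S_pow, E_Pt[lo:hi], A, S_noise
            )
            flat = aff.reshape(hi - lo, -1)
            if K > 1:
                # the rescue repairs shifts and orientations; the state label
                # belongs to the probabilistic sampler (a greedy cross-state
                # argmax here would drift labels toward the better state)
                for j in range(hi - lo):
                    s_j = cur_state[(lo + j) // T]
                    keep = slice(s_j * MA, (s_j + 1) * MA)
                    masked = np.full(flat.shape[1], -np.inf, dtype=flat.dtype)
                    masked[keep] = flat[j, keep]
                    flat[j] = masked
            cells = flat.argmax(axis=1)
            costs = 1.0 - flat[np.arange(hi - lo), cells]
            for j in range(hi - lo):
                p, t = divmod(lo + j, T)
                if costs[j] < best_cost[p]:
                    best_cost[p] = costs[j]
                    best_cell[p] = cells[j]
                    best_trial[p] = t
        improved = best_cost < chosen_cost[resc] - 1e-9
        for r_i in np.flatnonzero(improved):
            p = resc[r_i]
            chosen[p] = best_cell[r_i]
            chosen_cost[p] = best_cost[r_i]
            self.shifts[idx[r_i]] = cand[r_i, best_trial[r_i]] / scale

    # Damping of per-iteration shift updates: the stochastic orientation
    # resampling perturbs the per-iteration shift optimum, and an undamped
    # update chases that jitter; relaxing halfway suppresses it while still
    # converging within a stage.
    SHIFT_DAMP = 0.5

    def _refine_shifts(self, sd, refs, sel, rots, states_new, w):
        """Bounded quasi-Newton origin-shift refinement per sampled particle.

        The optimizer is started both from the particle's previous shift and
        from zero (the latter lets particles escape a self-consistent wrong
        (orientation, shift) pair); the lower-cost optimum wins.
        """
        bound = self.cfg.shift_bound * sd.box / self.m.box
        pts, lab = sd.disc_pts, sd.disc_lab
        c = 2.0 * np.pi / sd.box
        for k in range(self.K_active):
            which = np.flatnonzero(states_new == k)
            if not len(which):
                continue
            slices = refs[k].extract_slices(rots[which], pts)
            # the extra zero start is reserved for poorly matching particles:
            # only they profit from escaping the current shift basin
            bad_cost = np.quantile(np.nan_to_num(self.costs[sel], posinf=1.0), 0.7)
            for j, idx in enumerate(which):
                p_i = sel[idx]
                pvals = sd.fts[p_i].reshape(-1)[sd.disc_sel]
                hvals = sd.ctf2d[p_i].reshape(-1)[sd.disc_sel]
                rvals = hvals * slices[j]
                wv = w[idx][lab]
                s0 = self.shifts[p_i] * sd.box / self.m.box
                best, fbest = _shift_opt(pvals, rvals, wv, pts, c, s0, bound)
                if np.any(s0 != 0) and self.costs[p_i] > bad_cost:
                    alt, falt = _shift_opt(pvals, rvals, wv, pts, c, np.zeros(2), bound)
                    if falt < fbest:
                        best, fbest = alt, falt
                s_new = s0 + self.SHIFT_DAMP * (best - s0)
                self.shifts[p_i] = s_new * self.m.box / sd.box

    def _reconstruct_all(self, sd, sel, mode: str):
        """Per-state half-set reconstruction of the sampled particles."""
        K = self.K_active
        labels, rescued = rescue_empty_states(
            self.states.labels, K, -np.nan_to_num(self.costs, posinf=1e3), self.rng, 4
        )
        if rescued:
            self.states.labels = labels
            self._log(f"re-seeded empty state(s) {rescued}")
        vols = []
        recons = []
        shifts_px = self.shifts * sd.box / self.m.box
        for k in range(K):
            members = sel[self.states.labels[sel] == k]
            if len(members) < 4:
                members = sel  # degenerate: fall back to everything
            rots = self.rots[members]
            if len(self.sym_ops) > 1:
                rots = np.concatenate([self.sym_ops[g] @ rots for g in range(len(self.sym_ops))])
                members_x = np.tile(members, len(self.sym_ops))
            else:
                members_x = members
            half_ids = members_x % 2
            if half_ids.min() == half_ids.max():
                # degenerate small state with single-parity membership:
                # fall back to positional alternation for this rebuild
                half_ids = np.arange(len(members_x)) % 2
            recon = reconstruct_halfmaps(
                sd.fts[members_x],
                sd.ctf2d[members_x],
                rots,
                shifts_px[members_x],
                self.state_conf[members_x] if K > 1 else None,
                sd.apix,
                max_radius=sd.r_lp,
                half_ids=half_ids,
            )
            edge = max(2.0, sd.box / 16)
            radius = min(
                0.5 * self.cfg.mask_diameter_frac * sd.box, sd.box / 2 - edge - 0.5
            )
            vol = finalize_map(
                recon,
                mode=mode,
                mask_radius=radius,
                mask_edge=edge,
                reg_cfg=self.reg_cfg,
            )
            vols.append(vol)
            recons.append(recon)
        self.state_fsc = [r.fsc for r in recons]
        return vols, recons

    # -- results ------------------------------------------------------------

    def _results(self, last, runtime) -> AbInitioResults:
        sd, recons = last
        final_vols = []
        half_maps = []
        fscs = []
        for k in range(self.K_active):
            v = self.volumes[k]
            final_vols.append(resample_volume(v, self.m.box))
            half_maps.append(
                (
                    resample_volume(recons[k].even_map, self.m.box),
                    resample_volume(recons[k].odd_map, self.m.box),
                )
            )
            fscs.append(fsc_curve(half_maps[-1][0], half_maps[-1][1]))
        table = self._particle_table()
        return AbInitioResults(
            volumes=final_vols,
            half_maps=half_maps,
            fsc_curves=fscs,
            particle_table=table,
            march_plan=self.march,
            eps_history=self.eps_history,
            cost_history=self.cost_history,
            lp_history=self.lp_history,
            state_counts=self.states.counts(),
            config=self.cfg,
            runtime_s=runtime,
            log=self.log,
        )

    def _particle_table(self) -> pd.DataFrame:
        eul = np.array([matrix_to_euler_zyz(r) for r in self.rots])
        cls_of = np.zeros(self.m.n_particles, dtype=int)
        score_of = np.zeros(self.m.n_particles)
        for ci in self.m.classes:
            cls_of[ci.members] = ci.class_id
            score_of[ci.members] = ci.scores
        cp = self.m.ctf_params
        return pd.DataFrame(
            {
                "index": np.arange(self.m.n_particles),
                "defocus_u": [c.defocus_u for c in cp],
                "defocus_v": [c.defocus_v for c in cp],
                "astig_angle": [c.astig_angle for c in cp],
                "voltage": [c.voltage for c in cp],
                "cs": [c.cs for c in cp],
                "amp_contrast": [c.amp_contrast for c in cp],
                "class_id": cls_of,
                "class_score": score_of,
                "phi": eul[:, 0],
                "theta": eul[:, 1],
                "psi": eul[:, 2],
                "shift_x": self.shifts[:, 0],
                "shift_y": self.shifts[:, 1],
                "state": self.states.labels,
                "half": np.arange(self.m.n_particles) % 2,
                "cost": self.costs,
                "n_updates": self.n_updates,
            }
        )


# ---------------------------------------------------------------------------
# stage-level cached data
# ---------------------------------------------------------------------------


class _StageData:
    """Downscaled particle data and grids shared by one stage's iterations."""

    def __init__(self, runner: _Runner, stage, box, apix, lp):
        m = runner.m
        cfg = runner.cfg
        self.box = box
        self.apix = apix
        self.orig_box = m.box
        self.d_total = runner.d_total
        scfg = stage_config(stage)
        self.fts = fourier_crop_stack(runner.full_fts, box)
        self.images = np.real(ift2(self.fts)).astype(np.float32)
        self.ctf_params_list = m.ctf_params
        self.ctf2d = np.stack(
            [ctf_image(cp, box, apix) for cp in m.ctf_params]
        ).astype(np.float32)
        self.r_cap = box // 2 - 1
        self._cfg = cfg
        self._scfg = scfg
        self.r_lp = -1
        self._polar_cache = {}
        self.set_lowpass(lp)

    def set_lowpass(self, lp: float):
        r = int(np.clip(round(self.d_total / lp), 3, self.r_cap))
        if r == self.r_lp:
            return
        self.r_lp = r
        # the orientation grid tracks the current resolution (the dynamic
        # limit can move within a stage), capped by the stage's maximum
        delta = self._cfg.angular_oversampling / r
        n_m = int(
            min(self._scfg.max_directions, max(30, round(4 * np.pi / delta**2)))
        )
        n_n = _nice_len(max(12, round(2 * np.pi / delta)))
        self.grid = build_so3_grid(n_m, n_n, self._cfg.symmetry)
        self.spacing = max(self.grid.direction_spacing(), 360.0 / n_n / 2)
        if r not in self._polar_cache:
            rings = np.arange(1, r + 1, dtype=float)
            from .fourier import image_polar_sections

            A = self.grid.n_inplane
            polar = image_polar_sections(self.images, rings, A)
            th = np.arange(A) * (2 * np.pi / A)
            x = rings[:, None] * np.cos(th)[None, :]
            y = rings[:, None] * np.sin(th)[None, :]
            freq = rings / self.d_total
            az = th
            ctfp = self._ctf_polar(freq, az)
            h = np.arange(self.box) - self.box // 2
            hx, hy = np.meshgrid(h, h, indexing="ij")
            rr = np.hypot(hx, hy).ravel()
            disc_sel = np.flatnonzero((rr >= 1) & (rr <= r))
            pts = np.stack(
                [hx.ravel()[disc_sel], hy.ravel()[disc_sel]], axis=1
            ).astype(np.float32)
            lab = np.clip(np.round(rr[disc_sel]).astype(int) - 1, 0, r - 1)
            self._polar_cache[r] = (
                rings,
                polar,
                ctfp,
                x.astype(np.float32),
                y.astype(np.float32),
                np.round(2 * np.pi * rings),
                disc_sel,
                pts,
                lab,
            )
        (
            self.rings,
            self.polar,
            self.ctf_polar,
            self.ring_x,
            self.ring_y,
            self.ring_counts,
            self.disc_sel,
            self.disc_pts,
            self.disc_lab,
        ) = self._polar_cache[r]

    def _ctf_polar(self, freq, az):
        from .fourier import ctf_eval

        out = np.empty((len(self.ctf2d), len(freq), len(az)), dtype=np.float32)
        for i, cp in enumerate(self.ctf_params_list):
            out[i] = ctf_eval(cp, freq[:, None], az[None, :])
        return out

    def shift_ramp(self, shifts):
        """Polar recentering ramp for per-particle shifts (original px)."""
        s = np.asarray(shifts) * (self.box / self.orig_box)  # -> stage px
        c = 2.0 * np.pi / self.box
        phase = c * (
            self.ring_x[None] * s[:, 0, None, None]
            + self.ring_y[None] * s[:, 1, None, None]
        )
        return np.exp(1j * phase).astype(np.complex64)


def _nice_len(n: int) -> int:
    from .fourier import fft_friendly_size

    return fft_friendly_size(n)


def _rotz_batch(angles_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    out = np.zeros((len(angles_rad), 3, 3))
    out[:, 0, 0] = c
    out[:, 0, 1] = -s
    out[:, 1, 0] = s
    out[:, 1, 1] = c
    out[:, 2, 2] = 1.0
    return out


def _map_rotations(rots: np.ndarray, grid: SO3Grid):
    """Nearest grid cell (direction, in-plane) for arbitrary rotations."""
    dirs = rots[:, :, 2]
    m = np.argmax(dirs @ grid.directions.T, axis=1)
    rel = np.einsum("nji,njk->nik", grid.dir_rots[m], rots)  # dir^T @ R = Rz(psi)
    psi = np.arctan2(rel[:, 1, 0], rel[:, 0, 0])
    A = grid.n_inplane
    a = np.round(-psi / (2 * np.pi / A)).astype(int) % A
    return m, a


def _affinity_of(cells, affs, pick):
    j = np.flatnonzero(cells == pick)
    return float(affs[j[0]]) if len(j) else 0.0


def _shift_opt(pvals, rvals, w, pts, c, s0, bound):
    """L-BFGS-B on the normalized cost over the shift (disc-point form).

    Returns (shift, cost at shift).
    """
    hx = pts[:, 0].astype(np.float64)
    hy = pts[:, 1].astype(np.float64)
    p0 = pvals.astype(np.complex128)
    r = rvals.astype(np.complex128)
    wr = w.astype(np.float64)
    den = 2.0 * np.sum(wr * (np.abs(p0) ** 2 + np.abs(r) ** 2))
    if den <= 0:
        return s0, np.inf

    def fun(s):
        ramp = np.exp(1j * c * (hx * s[0] + hy * s[1]))
        p = p0 * ramp
        diff = p - r
        num = np.sum(wr * np.abs(diff) ** 2)
        gx = 2.0 * np.sum(wr * np.real(np.conj(diff) * (1j * c * hx * p)))
        gy = 2.0 * np.sum(wr * np.real(np.conj(diff) * (1j * c * hy * p)))
        return num / den, np.array([gx, gy]) / den

    try:
        res = minimize(
            fun,
            np.clip(s0, -bound, bound),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-bound, bound)] * 2,
            options={"maxiter": 30, "gtol": 1e-6},
        )
        if np.isfinite(res.fun):
            return res.x, float(res.fun)
    except (ValueError, FloatingPointError):
        pass
    return s0, fun(np.clip(s0, -bound, bound))[0]
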
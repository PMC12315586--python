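"""Rotations, S2/S1 grids and point-group symmetry.

Conventions
-----------
Rotations are right-handed 3x3 matrices acting on Fourier-space coordinates:
the central section of a volume at orientation ``R`` samples the 3D transform
at ``R @ (hx, hy, 0)``. The projection direction (the real-space axis summed
over) is ``R @ z_hat``. A full grid orientation factors as
``R = R_dir(m) @ Rz(psi_n)`` where ``R_dir`` maps ``z_hat`` onto the S2
direction and ``psi_n`` is the in-plane angle, i.e. ZYZ Euler angles
``(phi_m, theta_m, psi_n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_zyz_to_matrix(phi_deg: float, theta_deg: float, psi_deg: float) -> np.ndarray:
    """R = Rz(phi) @ Ry(theta) @ Rz(psi), angles in degrees."""
    return (
        rot_z(np.deg2rad(phi_deg))
        @ rot_y(np.deg2rad(theta_deg))
        @ rot_z(np.deg2rad(psi_deg))
    )


def matrix_to_euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_zyz_to_matrix`; returns degrees."""
    theta = np.arccos(np.clip(R[2, 2], -1.0, 1.0))
    if np.sin(theta) > 1e-8:
        phi = np.arctan2(R[1, 2], R[0, 2])
        psi = np.arctan2(R[2, 1], -R[2, 0])
    else:  # gimbal: fold everything into psi
        phi = 0.0
        if R[2, 2] > 0:
            psi = np.arctan2(R[1, 0], R[0, 0])
        else:
            psi = -np.arctan2(R[1, 0], R[0, 0])
    return float(np.rad2deg(phi)), float(np.rad2deg(theta)), float(np.rad2deg(psi))


def rotation_angle(R: np.ndarray) -> float:
    """Geodesic rotation angle of R in degrees."""
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.rad2deg(np.arccos(tr)))


def rotation_angles(Rs: np.ndarray) -> np.ndarray:
    tr = np.clip((np.trace(Rs, axis1=-2, axis2=-1) - 1.0) / 2.0, -1.0, 1.0)
    return np.rad2deg(np.arccos(tr))


def direction_to_matrix(d: np.ndarray) -> np.ndarray:
    """Rotation mapping z_hat to unit vector d: Rz(phi) @ Ry(theta)."""
    d = np.asarray(d, dtype=float)
    theta = np.arccos(np.clip(d[2], -1.0, 1.0))
    phi = np.arctan2(d[1], d[0]) if (d[0] ** 2 + d[1] ** 2) > 1e-16 else 0.0
    return rot_z(phi) @ rot_y(theta)


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices, shape (n, 3, 3) (Shoemake quaternions)."""
    u1, u2, u3 = rng.random((3, n))
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    return quat_to_matrix(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - z * w)
    R[..., 0, 2] = 2 * (x * z + y * w)
    R[..., 1, 0] = 2 * (x * y + z * w)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - x * w)
    R[..., 2, 0] = 2 * (x * z - y * w)
    R[..., 2, 1] = 2 * (y * z + x * w)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    k = v / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    angle = np.deg2rad(rotation_angle(R))
    if angle < 1e-8:
        return np.zeros(3)
    ax = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(ax)
    if n < 1e-12:  # angle ~ pi
        # axis from R + I column with largest norm
        M = R + np.eye(3)
        ax = M[:, np.argmax(np.sum(M * M, axis=0))]
        ax = ax / np.linalg.norm(ax)
        return ax * angle
    return ax / n * angle


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the full unit sphere (golden-angle spiral)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def parse_symmetry(label: str) -> tuple[str, int]:
    label = label.strip().upper()
    if not label or label[0] not in "CD" or not label[1:].isdigit():
        raise ValueError(f"unsupported symmetry label: {label!r}")
    fold = int(label[1:])
    if fold < 1 or (label[0] == "D" and fold < 2):
        raise ValueError(f"unsupported symmetry label: {label!r}")
    return label[0], fold


def symmetry_ops(label: str) -> np.ndarray:
    """Rotation matrices of the point group (identity first)."""
    family, n = parse_symmetry(label)
    ops = [rot_z(2 * np.pi * k / n) for k in range(n)]
    if family == "D":
        flip = rot_x(np.pi)
        ops += [flip @ op for op in ops[:n]]
    return np.stack(ops)


def in_asymmetric_unit(directions: np.ndarray, label: str) -> np.ndarray:
    """Boolean mask of directions inside the point-group asymmetric unit.

    C1: whole sphere. Cn: azimuth in [0, 2*pi/n). Dn: additionally z >= 0.
    """
    family, n = parse_symmetry(label)
    az = np.mod(np.arctan2(directions[:, 1], directions[:, 0]), 2 * np.pi)
    keep = az < (2 * np.pi / n + 1e-12)
    if n == 1 and family == "C":
        keep = np.ones(len(directions), dtype=bool)
    if family == "D":
        keep &= directions[:, 2] >= -1e-12
    return keep


def geodesic_s2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle angle(s) between unit vectors, degrees. Broadcasts."""
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


@dataclass
class SO3Grid:
    """Discrete orientation grid: N_m S2 directions x N_n in-plane angles."""

    directions: np.ndarray  # (N_m, 3)
    inplane_deg: np.ndarray  # (N_n,)
    symmetry: str = "C1"
    dir_rots: np.ndarray = field(init=False)  # (N_m, 3, 3)

    def __post_init__(self):
        self.dir_rots = np.stack([direction_to_matrix(d) for d in self.directions])

    @property
    def n_dirs(self) -> int:
        return len(self.directions)

    @property
    def n_inplane(self) -> int:
        return len(self.inplane_deg)

    @property
    def size(self) -> int:
        return self.n_dirs * self.n_inplane

    def rotation(self, m: int, n: int) -> np.ndarray:
        return self.dir_rots[m] @ rot_z(np.deg2rad(self.inplane_deg[n]))

    def cell_to_mn(self, cell: np.ndarray | int):
        return np.divmod(cell, self.n_inplane)

    def mn_to_cell(self, m, n):
        return m * self.n_inplane + n

    def direction_spacing(self) -> float:
        """Median nearest-neighbour S2 spacing, degrees."""
        if self.n_dirs == 1:
            return float(360.0 / max(self.n_inplane, 1))
        d = self.directions
        dot = np.clip(d @ d.T, -1.0, 1.0)
        np.fill_diagonal(dot, -1.0)
        return float(np.median(np.rad2deg(np.arccos(np.max(dot, axis=1)))))

    def geodesic_dirs(self, m1, m2) -> np.ndarray:
        """S2 geodesic angle between direction indices, degrees."""
        return geodesic_s2(self.directions[m1], self.directions[m2])


def build_so3_grid(n_dirs: int, n_inplane: int, symmetry: str = "C1") -> SO3Grid:
    """Fibonacci-sphere S2 grid filtered to the asymmetric unit, uniform S1.

    ``n_dirs`` is the full-sphere target count; higher point-group order
    retains proportionally fewer directions.
    """
    if n_dirs < 1 or n_inplane < 1:
        raise ValueError("n_dirs and n_inplane must be >= 1")
    parse_symmetry(symmetry)
    dirs = fibonacci_sphere(n_dirs)
    keep = in_asymmetric_unit(dirs, symmetry)
    if not np.any(keep):
        keep[0] = True
    return SO3Grid(
        directions=dirs[keep],
        inplane_deg=np.arange(n_inplane) * (360.0 / n_inplane),
        symmetry=symmetry,
    )


def project_to_so3(M: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix to M (orthogonal Procrustes)."""
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


_MIRROR = np.diag([1.0, 1.0, -1.0])


def align_orientations(
    est: np.ndarray, true: np.ndarray, symmetry: str = "C1"
) -> tuple[np.ndarray, bool, np.ndarray]:
    """Best global rotation (and hand) relating estimated to true rotations.

    A reconstructed frame relates to the generating frame by an arbitrary
    global rotation G and possibly a hand flip: est_i ~ G @ g_i @ true_i
    (g_i a symmetry operator), or with true_i replaced by M true_i M for the
    mirrored hand. Returns (G, flipped, per-particle angular errors in deg).
    """
    ops = symmetry_ops(symmetry)
    best = None
    for flipped in (False, True):
        T = _MIRROR @ true @ _MIRROR if flipped else true
        g_idx = np.zeros(len(T), dtype=int)
        G = np.eye(3)
        for _ in range(4):
            Tg = ops[g_idx] @ T
            G = project_to_so3(np.einsum("nij,nkj->ik", est, Tg))
            # reassign symmetry operators per particle
            if len(ops) > 1:
                errs = np.empty((len(ops), len(T)))
                for k, g in enumerate(ops):
                    errs[k] = rotation_angles(
                        np.einsum("nij,nkj->nik", est, (G @ g) @ T)
                    )
                g_idx = np.argmin(errs, axis=0)
        Tg = ops[g_idx] @ T
        errors = rotation_angles(np.einsum("nij,nkj->nik", est, np.matmul(G, Tg)))
        med = np.median(errors)
        if best is None or med < best[3]:
            best = (G, flipped, errors, med)
    return best[0], best[1], best[2]
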
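"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the data the analysis consumes:

* :func:`make_two_domain_structure` — a toy two-domain "hinge" protein whose
  inter-site Calpha-Calpha distance is controlled in closed form.  Both
  domains are rigid helical Calpha bundles attached to a common pivot; the
  designated tag-site residue of each domain sits at the tip of an arm of
  length ``arm_length`` from the pivot, and the two arms open symmetrically
  in a plane.  With base angle gamma0 and opening angle theta (degrees), the
  inter-site distance is

      d(theta) = 2 * arm_length * sin((gamma0 + theta) / 2)     [closed form]

  which is strictly increasing for gamma0 + theta < 180 deg.  A state-
  dependent "twist" of the mobile domain about its own arm axis adds a
  second conformational coordinate that leaves d unchanged — emulating
  open vs wide-open conformers that overlap in distance but differ in
  overall shape.

* :func:`make_trajectory` — a Markov chain over named conformational states,
  each with a mean inter-site distance and Gaussian jitter, rendered as full
  coordinate snapshots (stride 0.1 ns by default, the sampling used for the
  reference simulations).

* :func:`make_deer_dataset` — a noisy DEER trace generated from a Gaussian-
  mixture distance distribution with stretched-exponential background, plus
  the exact generating density for recovery scoring.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import deer
from .structio import AtomRecord, Structure, SiteRef

__all__ = [
    "HingeSpec",
    "TrajectorySpec",
    "StateSpec",
    "DeerGroundTruth",
    "Snapshot",
    "hinge_site_distance",
    "hinge_angle_for_distance",
    "make_two_domain_structure",
    "make_trajectory",
    "make_deer_dataset",
]

# Hinge geometry defaults (Angstrom / degrees).  arm 25 A and base angle 30
# deg span inter-site distances 1.29-4.83 nm over theta in [0, 120], covering
# the 2.5-4.8 nm range where the closed/open/wide-open windows of the study
# proteins live.
ARM_LENGTH = 25.0
BASE_ANGLE = 30.0


def hinge_site_distance(theta: float, arm_length: float = ARM_LENGTH, base_angle: float = BASE_ANGLE) -> float:
    """Closed-form inter-site Calpha-Calpha distance d(theta), nm."""
    if not 0.0 <= theta <= 120.0:
        raise ValueError("opening angle theta must lie in [0, 120] degrees")
    return 2.0 * arm_length * math.sin(math.radians((base_angle + theta) / 2.0)) / 10.0


def hinge_angle_for_distance(d_nm: float, arm_length: float = ARM_LENGTH, base_angle: float = BASE_ANGLE) -> float:
    """Invert d(theta): opening angle (degrees) giving the target distance."""
    s = d_nm * 10.0 / (2.0 * arm_length)
    if not 0.0 < s < 1.0:
        raise ValueError(f"distance {d_nm} nm out of reach for arm length {arm_length} A")
    theta = 2.0 * math.degrees(math.asin(s)) - base_angle
    if not 0.0 <= theta <= 120.0:
        raise ValueError(f"distance {d_nm} nm requires theta outside [0, 120] degrees")
    return theta


@dataclass(frozen=True)
class HingeSpec:
    """Two-domain hinge structure with controlled openness."""

    theta: float = 30.0            # opening angle, degrees, in [0, 120]
    n_res_per_domain: int = 30
    site_res: int = 15             # tag-site residue index within each chain
    twist: float = 0.0             # rotation of chain B about its arm axis, degrees
    jitter_sd: float = 0.0         # per-atom Gaussian displacement, Angstrom
    seed: int = 0
    arm_length: float = ARM_LENGTH
    base_angle: float = BASE_ANGLE

    def __post_init__(self):
        if not 0.0 <= self.theta <= 120.0:
            raise ValueError("theta must lie in [0, 120] degrees")
        if not 1 <= self.site_res <= self.n_res_per_domain:
            raise ValueError("site residue must exist within the domain")

    @property
    def site_a(self) -> SiteRef:
        return SiteRef("A", self.site_res)

    @property
    def site_b(self) -> SiteRef:
        return SiteRef("B", self.site_res)


def _helix_backbone(n_res: int) -> dict[int, dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone in a local frame (helix axis = +x).

    Calpha for every residue; N, C and CB only where a full frame is needed
    (they are emitted just for the tag-site residue).
    """
    rise, radius, turn = 1.5, 2.3, math.radians(100.0)
    out: dict[int, dict[str, np.ndarray]] = {}
    for i in range(n_res):
        phi = i * turn
        ca = np.array([i * rise, radius * math.cos(phi), radius * math.sin(phi)])
        # offsets chosen to give a plausible non-degenerate backbone frame
        n = ca + np.array([-1.20, 0.70, -0.45])
        c = ca + np.array([1.25, 0.60, 0.55])
        out[i + 1] = {"N": n, "CA": ca, "C": c}
    return out


def make_two_domain_structure(spec: HingeSpec) -> Structure:
    """Build the hinge structure; chain A is fixed, chain B opens by theta."""
    alpha = math.radians((spec.base_angle + spec.theta) / 2.0)
    dir_a = np.array([-math.sin(alpha), math.cos(alpha), 0.0])
    dir_b = np.array([math.sin(alpha), math.cos(alpha), 0.0])

    def rot_z(angle: float) -> np.ndarray:
        c, s = math.cos(angle), math.sin(angle)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
        a = axis / np.linalg.norm(axis)
        th = math.radians(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)

    backbone = _helix_backbone(spec.n_res_per_domain)
    site_local = backbone[spec.site_res]["CA"]

    atoms: list[AtomRecord] = []
    rng = np.random.default_rng(spec.seed)
    for chain, direction, extra_rot in (
        ("A", dir_a, np.eye(3)),
        ("B", dir_b, axis_rotation(dir_b, spec.twist)),
    ):
        # local +x -> outward arm direction; site CA lands at arm tip
        base = rot_z(math.atan2(direction[1], direction[0]))
        R = extra_rot @ base
        tip = spec.arm_length * direction
        for res, names in backbone.items():
            emit = ("N", "CA", "C") if res == spec.site_res else ("CA",)
            for name in emit:
                xyz = tip + R @ (names[name] - site_local)
                if spec.jitter_sd > 0:
                    xyz = xyz + rng.normal(0.0, spec.jitter_sd, 3)
                atoms.append(
                    AtomRecord(name, "C" if name != "N" else "N", "ALA", res, chain, xyz)
                )

    s = Structure(atoms, provenance=f"hinge(theta={spec.theta:g})", numbering_offset_applied=0)
    # guard against inter-domain collision at extreme closure
    xa = s.coordinates(lambda a: a.chain_id == "A")
    xb = s.coordinates(lambda a: a.chain_id == "B")
    dmin = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min()
    if dmin < 0.8:
        raise ValueError(f"domains collide at theta={spec.theta:g} (closest approach {dmin:.2f} A)")
    return s


# --------------------------------------------------------------------------
# Markov state-switching trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpec:
    name: str
    ca_mean: float          # nm
    ca_sd: float            # nm
    twist_mean: float = 0.0  # degrees, second conformational coordinate
    twist_sd: float = 0.0


@dataclass
class TrajectorySpec:
    states: list[StateSpec]
    transition: np.ndarray     # row-stochastic matrix, one row per state
    n_frames: int = 1000
    stride_ns: float = 0.1
    seed: int = 0
    build_structures: bool = True

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        n = len(self.states)
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix shape must match the state count")
        if np.any(self.transition < 0) or not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class Snapshot:
    time_ns: float
    ca_distance: float            # nm
    rg: float                     # nm (NaN when structures are not built)
    label_true: str
    structure: Structure | None = None


def make_trajectory(spec: TrajectorySpec) -> list[Snapshot]:
    """Markov-switching snapshot series with per-state distance jitter."""
    from .structio import ca_distance, radius_of_gyration

    rng = np.random.default_rng(spec.seed)
    n_states = len(spec.states)
    pi = spec.stationary_distribution()
    state = int(rng.choice(n_states, p=pi))
    snapshots: list[Snapshot] = []
    for i in range(spec.n_frames):
        st = spec.states[state]
        d = float(rng.normal(st.ca_mean, st.ca_sd)) if st.ca_sd > 0 else st.ca_mean
        twist = float(rng.normal(st.twist_mean, st.twist_sd)) if st.twist_sd > 0 else st.twist_mean
        struct = None
        rg = float("nan")
        if spec.build_structures:
            theta = hinge_angle_for_distance(d)
            struct = make_two_domain_structure(HingeSpec(theta=theta, twist=twist))
            d = ca_distance(struct, SiteRef("A", 15), SiteRef("B", 15))
            rg = radius_of_gyration(struct)
        snapshots.append(Snapshot(i * spec.stride_ns, d, rg, st.name, struct))
        state = int(rng.choice(n_states, p=spec.transition[state]))
    return snapshots


# --------------------------------------------------------------------------
# DEER ground truth
# --------------------------------------------------------------------------

@dataclass
class DeerGroundTruth:
    """Gaussian-mixture distance truth plus acquisition parameters."""

    means: tuple = (3.2, 4.4)      # nm
    sds: tuple = (0.15, 0.15)      # nm
    weights: tuple = (0.5, 0.5)
    modulation_depth: float = 0.3
    background_k: float = 0.15     # 1/us
    background_d: float = 3.0
    snr: float = 50.0
    t_max: float = 4.0             # us
    dt: float = 0.008              # us
    seed: int = 0
    r_grid: np.ndarray = field(default_factory=deer.default_r_grid)


def make_deer_dataset(truth: DeerGroundTruth) -> tuple[deer.DeerTrace, deer.DistanceDistribution]:
    """Noisy trace plus the exact generating density."""
    p = deer.DistanceDistribution.from_gaussians(truth.r_grid, truth.means, truth.sds, truth.weights)
    trace = deer.simulate_trace(
        p,
        truth.modulation_depth,
        (truth.background_k, truth.background_d),
        snr=truth.snr,
        seed=truth.seed,
        t_max=truth.t_max,
        dt=truth.dt,
    )
    return trace, p
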
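"""Conformational-state classification and population estimation.

Solute-binding-protein conformers are binned into named states (closed,
open, wide-open) by the inter-site Calpha-Calpha distance between the two
tagged residues; where two windows overlap, a frame is "ambiguous" and can
be resolved by principal component analysis of the superposed Calpha
coordinates, splitting along PC1 with a deterministic 2-means and mapping
the clusters back to states via the unambiguous frames' mean distances.

State populations come from two routes: fractions of classified trajectory
frames, or integrals of a DEER distance distribution over each state's
modelled Gd-Gd window.  The per-protein windows reported for the study
proteins ship as package data (``data/state_definitions.yaml``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .deer import DistanceDistribution

__all__ = [
    "StateDefinition",
    "StatePopulations",
    "load_state_definitions",
    "builtin_state_definitions",
    "classify_snapshot",
    "classify_trajectory",
    "pca_disambiguate",
    "populations_from_trajectory",
    "populations_from_distribution",
]

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class StateDefinition:
    """A named conformational window on the Calpha-Calpha axis (nm), with
    the equivalent modelled Gd-Gd window where known."""

    name: str
    ca_range: tuple[float, float]
    gd_range: tuple[float, float] | None = None

    def __post_init__(self):
        lo, hi = self.ca_range
        if not lo < hi:
            raise ValueError(f"state {self.name}: ca_range must satisfy lo < hi")
        if self.gd_range is not None and not self.gd_range[0] < self.gd_range[1]:
            raise ValueError(f"state {self.name}: gd_range must satisfy lo < hi")

    def contains_ca(self, d: float) -> bool:
        return self.ca_range[0] <= d <= self.ca_range[1]


@dataclass
class StatePopulations:
    """State -> fraction mapping; ambiguous/unassigned mass tracked apart."""

    fractions: dict[str, float]
    ambiguous: float = 0.0
    unassigned: float = 0.0

    def __post_init__(self):
        total = sum(self.fractions.values()) + self.ambiguous + self.unassigned
        if any(v < -1e-12 for v in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1 (got {total:.6f})")

    def __getitem__(self, name: str) -> float:
        return self.fractions.get(name, 0.0)


def load_state_definitions(text: str) -> dict[str, list[StateDefinition]]:
    """Parse per-protein state blocks from YAML text."""
    raw = yaml.safe_load(text)
    out: dict[str, list[StateDefinition]] = {}
    for protein, block in raw.items():
        defs = []
        for name, ranges in block.items():
            gd = tuple(ranges["gd"]) if "gd" in ranges else None
            defs.append(StateDefinition(name, tuple(ranges["ca"]), gd))
        out[protein] = defs
    return out


def builtin_state_definitions() -> dict[str, list[StateDefinition]]:
    """The per-protein windows of the study proteins (packaged config)."""
    text = resources.files("deerscape").joinpath("data/state_definitions.yaml").read_text()
    return load_state_definitions(text)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_snapshot(ca_distance: float, defs: list[StateDefinition]) -> str:
    """Label a frame by its Calpha-Calpha distance.

    Closed intervals on both ends; membership in more than one window yields
    "ambiguous", in none "unassigned".  Pure function of (distance, defs).
    """
    if not defs:
        raise ValueError("need at least one state definition")
    hits = [d.name for d in defs if d.contains_ca(ca_distance)]
    if len(hits) == 1:
        return hits[0]
    return AMBIGUOUS if hits else UNASSIGNED


def classify_trajectory(distances, defs: list[StateDefinition]) -> list[str]:
    return [classify_snapshot(float(d), defs) for d in distances]


def pca_disambiguate(
    coords: np.ndarray,
    ca_distances: np.ndarray,
    state_means: dict[str, float],
    variance_threshold: float = 1e-6,
) -> list[str]:
    """Split ambiguous frames into two states by PCA on superposed Calpha
    coordinates.

    ``coords`` is (n_frames, n_atoms, 3), already superposed on the rigid
    (large) domain; ``state_means`` maps the two candidate state names to
    their mean Calpha-Calpha distances from unambiguous frames.  PCA runs on
    the flattened coordinates; a deterministic 2-means seeded at the extreme
    PC1 scores splits the frames, and each cluster takes the name of the
    candidate state whose mean distance is closest to the cluster's own.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need at least two ambiguous frames of (n_atoms, 3) coordinates")
    if len(state_means) != 2:
        raise ValueError("pca_disambiguate resolves exactly two candidate states")
    X = coords.reshape(coords.shape[0], -1)
    Xc = X - X.mean(axis=0)
    # PC1 via SVD of the centred data matrix
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var1 = svals[0] ** 2 / max(coords.shape[0] - 1, 1)
    if var1 < variance_threshold:
        warnings.warn("PC1 variance below threshold; frames remain ambiguous")
        return [AMBIGUOUS] * coords.shape[0]
    pc1 = Xc @ vt[0]

    # deterministic 1-d 2-means initialized at the extreme scores
    centres = np.array([pc1.min(), pc1.max()])
    assign = np.zeros(len(pc1), dtype=int)
    for _ in range(100):
        new_assign = (np.abs(pc1[:, None] - centres[None, :])).argmin(axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            if np.any(assign == k):
                centres[k] = pc1[assign == k].mean()
    if len(np.unique(assign)) < 2:
        warnings.warn("2-means collapsed to a single cluster; frames remain ambiguous")
        return [AMBIGUOUS] * coords.shape[0]

    names = list(state_means)
    ca_distances = np.asarray(ca_distances, dtype=float)
    labels = [None, None]
    for k in (0, 1):
        cluster_mean = ca_distances[assign == k].mean()
        labels[k] = min(names, key=lambda n: abs(state_means[n] - cluster_mean))
    if labels[0] == labels[1]:
        # both clusters nearest the same state: order clusters by distance
        order = np.argsort([ca_distances[assign == k].mean() for k in (0, 1)])
        sorted_names = sorted(names, key=lambda n: state_means[n])
        labels = [None, None]
        for rank, k in enumerate(order):
            labels[k] = sorted_names[rank]
    return [labels[k] for k in assign]


# --------------------------------------------------------------------------
# Populations
# --------------------------------------------------------------------------

def populations_from_trajectory(labels, defs: list[StateDefinition]) -> StatePopulations:
    """Fractions of frames per state; ambiguous/unassigned kept separate."""
    labels = list(labels)
    if not labels:
        raise ValueError("trajectory has no frames")
    n = len(labels)
    fractions = {d.name: labels.count(d.name) / n for d in defs}
    return StatePopulations(
        fractions,
        ambiguous=labels.count(AMBIGUOUS) / n,
        unassigned=labels.count(UNASSIGNED) / n,
    )


def populations_from_distribution(
    p: DistanceDistribution, defs: list[StateDefinition]
) -> StatePopulations:
    """Integrate a Gd-Gd distance distribution over each state's window.

    Mass in a region covered by several overlapping windows is split equally
    among them; mass outside every window is reported as unassigned.
    """
    for d in defs:
        if d.gd_range is None:
            raise ValueError(f"state {d.name} has no Gd-Gd window")
    r, dens = p.r, p.density
    weights = {d.name: np.zeros_like(dens) for d in defs}
    cover = np.zeros_like(dens)
    masks = {}
    for d in defs:
        m = (r >= d.gd_range[0]) & (r <= d.gd_range[1])
        masks[d.name] = m
        cover += m
    for d in defs:
        m = masks[d.name]
        w = np.zeros_like(dens)
        w[m] = 1.0 / cover[m]
        weights[d.name] = w
    fractions = {
        name: float(np.trapezoid(dens * w, r)) for name, w in weights.items()
    }
    total = sum(fractions.values())
    unassigned = max(0.0, 1.0 - total)
    # guard tiny trapezoid overshoot at window edges
    if total > 1.0:
        fractions = {k: v / total for k, v in fractions.items()}
        unassigned = 0.0
    return StatePopulations(fractions, unassigned=unassigned)
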
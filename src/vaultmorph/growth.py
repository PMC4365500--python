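"""Stage-2 bone growth with morphogen-mediated suture formation.

After the primary ossification centers have formed, each is treated as a
separate bony element *i* carrying its own osteoblast field Co_i and its own
diffusible morphogen field Cm_i, secreted by the bone's osteoblasts.
Osteoblast differentiation at a cell requires that bone's morphogen to
exceed a threshold, saturates as the local osteoblast density approaches
CoS, and is vetoed wherever a *different* bone's morphogen exceeds the small
limitation level Cml:

    dCo_i/dt = lam * CoS^n/(Co_i^n + CoS^n)
                   * Cm_i^n/(Cm_i^n + CmT^n)
                   * prod_{j != i} Cml^n/(Cm_j^n + Cml^n)

    dCm_i/dt = alpha * Co_i * CmS^n/(Cm_i^n + CmS^n) + Dm * lap(Cm_i)

The mutual veto is the suture mechanism: bone fronts advancing toward each
other stall where they sense the other bone's morphogen, leaving a
persistent unossified gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import labeled_components
from .geometry import SurfaceMesh


class EmptyBoneSetError(ValueError):
    """No cell exceeds the ossification threshold when labeling bones."""


@dataclass
class GrowthParams:
    """Bone-growth and morphogen parameters.

    The Hill exponent ``n_growth`` defaults to 8, matching the sharpness
    used by the differentiation law (the growth-stage tabulation lists no
    separate exponent).
    """

    alpha: float = 5.0e-5   # morphogen production constant, 1/s
    CmS: float = 2.0        # morphogen saturation, ng/mm^3
    Dm: float = 1.2e-7      # morphogen diffusion, mm^2/s
    lam: float = 1.0e-1     # growth constant, ng/(mm^3 s)
    CoS: float = 1.0        # osteoblast saturation, ng/mm^3
    CmT: float = 2.0        # morphogen threshold, ng/mm^3
    Cml: float = 1.0e-3     # morphogen limitation (cross-bone veto), ng/mm^3
    n_growth: float = 8.0   # Hill exponent

    def validate(self) -> None:
        for name in ("alpha", "CmS", "Dm", "lam", "CoS", "CmT", "Cml",
                     "n_growth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BoneSet:
    """Labeled bony elements and their per-bone fields.

    ``labels`` assigns each cell its bone index (1..n_bones, 0 = unassigned)
    at labeling time; ``Co`` and ``Cm`` are (n_bones, n_cells) arrays. Bone
    indices are ordered rostral-to-caudal, then left-to-right, so they are
    stable across runs and resolutions.
    """

    n_bones: int
    labels: np.ndarray
    Co: np.ndarray
    Cm: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.Co = np.asarray(self.Co, dtype=float)
        self.Cm = np.asarray(self.Cm, dtype=float)

    def total_Co(self) -> np.ndarray:
        return self.Co.sum(axis=0)

    def copy(self) -> "BoneSet":
        return BoneSet(self.n_bones, self.labels.copy(), self.Co.copy(),
                       self.Cm.copy())


def label_primary_centers(
    Co: np.ndarray, mesh: SurfaceMesh, threshold: float = 1.0
) -> BoneSet:
    """Split the stage-1 osteoblast field into bones at the given threshold.

    Connected components (edge adjacency) of ``{Co > threshold}`` become
    bones; each bone's Co field is the stage-1 field restricted to its
    component (so the bones partition the supra-threshold osteoblast mass),
    and morphogen fields start at zero.
    """
    Co = np.asarray(Co, dtype=float)
    if np.any(Co < 0):
        raise ValueError("Co must be non-negative")
    comps = labeled_components(Co > threshold, mesh)
    if not comps:
        raise EmptyBoneSetError(
            f"no cell exceeds the ossification threshold {threshold}"
        )
    n = len(comps)
    labels = np.zeros(mesh.n_cells, dtype=np.int64)
    co = np.zeros((n, mesh.n_cells))
    for i, cells in enumerate(comps):
        labels[cells] = i + 1
        co[i, cells] = Co[cells]
    return BoneSet(n_bones=n, labels=labels, Co=co,
                   Cm=np.zeros((n, mesh.n_cells)))


def growth_rate(
    Co_i: np.ndarray | float,
    Cm_i: np.ndarray | float,
    Cm_others: list[np.ndarray] | list[float],
    p: GrowthParams,
) -> np.ndarray | float:
    """Osteoblast differentiation rate of bone *i* (ng mm^-3 s^-1), in [0, lam].

    Saturation factor (decreasing in Co_i), own-morphogen activation
    (increasing in Cm_i), and one veto factor per other bone (decreasing in
    that bone's morphogen).
    """
    Co_i = np.asarray(Co_i, dtype=float)
    Cm_i = np.asarray(Cm_i, dtype=float)
    if np.any(Co_i < 0) or np.any(Cm_i < 0):
        raise ValueError("concentrations must be non-negative")
    n = p.n_growth
    cos_n = p.CoS**n
    sat = cos_n / (Co_i**n + cos_n)
    cmt_n = p.CmT**n
    cm_n = Cm_i**n
    act = cm_n / (cm_n + cmt_n)
    rate = p.lam * sat * act
    cml_n = p.Cml**n
    for cm_j in Cm_others:
        cm_j = np.asarray(cm_j, dtype=float)
        if np.any(cm_j < 0):
            raise ValueError("concentrations must be non-negative")
        rate = rate * cml_n / (cm_j**n + cml_n)
    return float(rate) if np.ndim(rate) == 0 else rate


def morphogen_rate(
    Co_i: np.ndarray | float, Cm_i: np.ndarray | float, p: GrowthParams
) -> np.ndarray | float:
    """Reaction part of dCm_i/dt: secretion by osteoblasts, saturating in Cm_i.

    The solver adds the diffusion term ``Dm * lap(Cm_i)``. Value lies in
    [0, alpha * Co_i].
    """
    Co_i = np.asarray(Co_i, dtype=float)
    Cm_i = np.asarray(Cm_i, dtype=float)
    if np.any(Co_i < 0) or np.any(Cm_i < 0):
        raise ValueError("concentrations must be non-negative")
    n = p.n_growth
    cms_n = p.CmS**n
    rate = p.alpha * Co_i * cms_n / (Cm_i**n + cms_n)
    return float(rate) if np.ndim(rate) == 0 else rate
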
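"""Cohort designs: the ground truth a synthetic PBA experiment is drawn from.

A :class:`CohortDesign` specifies sample groups, the number of exosome
subpopulations K, a K x P signature matrix of per-protein detection weights,
per-group subpopulation mixing proportions, and the sequencing error model.
:func:`crc_cohort_design` packages the study conditions of the CRC cohort:
three groups (healthy controls, primary CRC, liver-metastatic CRC), twelve
subpopulations, a tumor-associated ITGA6/ITGB3-type cluster whose share rises
13.61% -> 23.03% -> 52.06% across groups, and a monocyte/macrophage-associated
ITGAM/ITGAL/ITGB2-type cluster falling 13.47% -> 1.13% -> 1.13%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .panel import PanelDefinition, default_panel


class DesignError(ValueError):
    """Raised when a cohort design violates its invariants."""


# Mixing proportions of the two signature clusters across the CRC cohorts.
TUMOR_CLUSTER = "ITGA6_ITGB3"
IMMUNE_CLUSTER = "ITGAM_ITGAL_ITGB2"
_TUMOR_MIX = {"HC": 0.1361, "CRC": 0.2303, "MET": 0.5206}
_IMMUNE_MIX = {"HC": 0.1347, "CRC": 0.0113, "MET": 0.0113}

#: Dominant marker blocks of the twelve planted subpopulations.  The first two
#: mirror the named tumor- and immune-associated clusters; the rest are
#: filler subpopulations over other panel markers.
DEFAULT_BLOCKS: dict[str, dict[str, float]] = {
    TUMOR_CLUSTER: {"ITGA6": 0.42, "ITGB3": 0.38, "ADAM10": 0.08,
                    "CD151": 0.06, "CD9": 0.06},
    IMMUNE_CLUSTER: {"ITGAM": 0.40, "ITGAL": 0.35, "ITGB2": 0.25},
    "EPS8_ILK": {"EPS8": 0.45, "ILK": 0.30, "RIOX2": 0.25},
    "NT5E_CCR2": {"NT5E": 0.40, "CCR2": 0.35, "THY1": 0.25},
    "TIMP1_MMP2": {"TIMP1": 0.40, "MMP2": 0.35, "EGFR": 0.25},
    "TETRASPANIN": {"CD81": 0.40, "CD63": 0.35, "TSG101": 0.25},
    "EPCAM_CD44": {"EPCAM": 0.40, "CD44": 0.35, "CD147": 0.25},
    "ERBB2_BM": {"ERBB2": 0.45, "BM001": 0.30, "BM002": 0.25},
    "BM_A": {"BM003": 0.40, "BM004": 0.35, "BM005": 0.25},
    "BM_B": {"BM006": 0.40, "BM007": 0.35, "BM008": 0.25},
    "BM_C": {"BM009": 0.40, "BM010": 0.35, "BM011": 0.25},
    "BM_D": {"BM012": 0.40, "BM013": 0.35, "BM014": 0.25},
}


@dataclass
class CohortDesign:
    """Ground-truth design of a synthetic single-exosome cohort."""

    groups: tuple[tuple[str, int], ...]
    n_clusters: int
    protein_names: tuple[str, ...]
    cluster_names: tuple[str, ...]
    signatures: np.ndarray  # (K, P) nonnegative detection weights
    mixing: dict[str, np.ndarray]  # group -> length-K proportions
    exosomes_per_sample: int = 3000
    molecules_per_exosome_mean: float = 2.4
    duplication_rate: float = 0.5
    substitution_rate: float = 0.0002
    low_quality_read_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        self.mixing = {g: np.asarray(v, dtype=float) for g, v in self.mixing.items()}
        self.validate()

    def validate(self) -> None:
        k, p = self.n_clusters, len(self.protein_names)
        if k < 1:
            raise DesignError("need at least one cluster")
        if self.signatures.shape != (k, p):
            raise DesignError(
                f"signatures shape {self.signatures.shape} != (K={k}, P={p})"
            )
        if (self.signatures < 0).any():
            raise DesignError("signature weights must be nonnegative")
        if (self.signatures.sum(axis=1) <= 0).any():
            raise DesignError("every signature row needs >= 1 positive weight")
        if len(self.cluster_names) != k:
            raise DesignError("cluster_names length must equal n_clusters")
        group_names = [g for g, _ in self.groups]
        if not set(group_names) <= set(self.mixing):
            raise DesignError("every group needs a mixing vector")
        for g, pi in self.mixing.items():
            if pi.shape != (k,):
                raise DesignError(f"mixing[{g}] must have length K={k}")
            if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
                raise DesignError(f"mixing[{g}] must be a probability vector")
        for _, n in self.groups:
            if n < 1:
                raise DesignError("each group needs >= 1 sample")
        if self.exosomes_per_sample < 1:
            raise DesignError("exosomes_per_sample must be positive")
        if self.molecules_per_exosome_mean < 1:
            raise DesignError("molecules_per_exosome_mean must be >= 1")
        for name in ("duplication_rate", "substitution_rate",
                     "low_quality_read_fraction"):
            v = getattr(self, name)
            if v < 0:
                raise DesignError(f"{name} must be nonnegative")
        if not 0 <= self.low_quality_read_fraction <= 1:
            raise DesignError("low_quality_read_fraction must be in [0, 1]")
        if not 0 <= self.substitution_rate <= 1:
            raise DesignError("substitution_rate must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1:02d}" for g, n in self.groups for i in range(n)]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_{i + 1:02d}": g for g, n in self.groups for i in range(n)}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "groups": [[g, int(n)] for g, n in self.groups],
            "n_clusters": int(self.n_clusters),
            "protein_names": list(self.protein_names),
            "cluster_names": list(self.cluster_names),
            "signatures": self.signatures.tolist(),
            "mixing": {g: v.tolist() for g, v in self.mixing.items()},
            "exosomes_per_sample": int(self.exosomes_per_sample),
            "molecules_per_exosome_mean": float(self.molecules_per_exosome_mean),
            "duplication_rate": float(self.duplication_rate),
            "substitution_rate": float(self.substitution_rate),
            "low_quality_read_fraction": float(self.low_quality_read_fraction),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortDesign":
        return cls(
            groups=tuple((g, int(n)) for g, n in d["groups"]),
            n_clusters=int(d["n_clusters"]),
            protein_names=tuple(d["protein_names"]),
            cluster_names=tuple(d["cluster_names"]),
            signatures=np.asarray(d["signatures"], dtype=float),
            mixing={g: np.asarray(v, dtype=float) for g, v in d["mixing"].items()},
            exosomes_per_sample=int(d["exosomes_per_sample"]),
            molecules_per_exosome_mean=float(d["molecules_per_exosome_mean"]),
            duplication_rate=float(d["duplication_rate"]),
            substitution_rate=float(d["substitution_rate"]),
            low_quality_read_fraction=float(d["low_quality_read_fraction"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_signatures(
    blocks: Mapping[str, Mapping[str, float]],
    protein_names: Sequence[str],
    background: float = 0.05,
) -> np.ndarray:
    """Build signature rows from dominant marker blocks.

    Each row puts ``1 - background`` of its mass on the block markers (scaled
    by their relative weights) and spreads ``background`` uniformly over the
    whole panel, mimicking sparse subpopulation signatures with a small
    nonspecific detection floor.
    """
    name_to_col = {n: j for j, n in enumerate(protein_names)}
    p = len(protein_names)
    sig = np.zeros((len(blocks), p))
    for i, (cluster, markers) in enumerate(blocks.items()):
        total = sum(markers.values())
        for marker, w in markers.items():
            if marker not in name_to_col:
                raise DesignError(f"block {cluster}: marker {marker} not in panel")
            sig[i, name_to_col[marker]] = (1.0 - background) * w / total
        sig[i] += background / p
    return sig


def crc_cohort_design(
    panel: PanelDefinition | None = None,
    exosomes_per_sample: int = 3000,
    background: float = 0.05,
) -> CohortDesign:
    """The packaged CRC-cohort-like fixture.

    Three groups — HC (n=13), primary CRC (n=10), liver-metastatic CRC
    (n=11) — with K=12 subpopulations.  The tumor-associated cluster mixes at
    13.61/23.03/52.06% and the immune-associated cluster at 13.47/1.13/1.13%
    across HC/CRC/MET; the ten remaining clusters share the residual mass
    equally.  Mean molecules per exosome is 2.4.
    """
    if panel is None:
        panel = default_panel()
    protein_names = panel.names
    blocks = DEFAULT_BLOCKS
    cluster_names = tuple(blocks)
    k = len(cluster_names)
    signatures = make_signatures(blocks, protein_names, background=background)

    mixing: dict[str, np.ndarray] = {}
    for group in ("HC", "CRC", "MET"):
        pi = np.empty(k)
        tumor, immune = _TUMOR_MIX[group], _IMMUNE_MIX[group]
        rest = (1.0 - tumor - immune) / (k - 2)
        pi[:] = rest
        pi[cluster_names.index(TUMOR_CLUSTER)] = tumor
        pi[cluster_names.index(IMMUNE_CLUSTER)] = immune
        mixing[group] = pi / pi.sum()

    return CohortDesign(
        groups=(("HC", 13), ("CRC", 10), ("MET", 11)),
        n_clusters=k,
        protein_names=protein_names,
        cluster_names=cluster_names,
        signatures=signatures,
        mixing=mixing,
        exosomes_per_sample=exosomes_per_sample,
    )
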
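"""Antibody panel and sequencing read layout for proximity barcoding assay (PBA) data.

In a PBA experiment each antibody carries an oligonucleotide with a short DNA
*protein tag* identifying the antibody, a *molecule tag* (UMI) unique to the
bound oligo, and — after the extension reaction on the vesicle surface — an
*exosome tag* shared by all oligos on the same vesicle.  The panel maps
antibody names to their protein-tag sequences; the read layout records where
each field sits inside a single-end sequencing read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {ord(b): i for i, b in enumerate(BASES)}

#: Surface markers highlighted in the CRC plasma-exosome panel: integrins and
#: adhesion/tetraspanin markers for the tumor-associated subpopulation
#: (ITGA6/ITGB3/ADAM10/CD151/CD9), leukocyte integrins for the
#: monocyte/macrophage-associated subpopulation (ITGAM/ITGAL/ITGB2), plus
#: other reported CRC-relevant exosomal proteins.
NAMED_MARKERS: tuple[str, ...] = (
    "ITGA6", "ITGB3", "ADAM10", "CD151", "CD9",
    "ITGAM", "ITGAL", "ITGB2",
    "EPS8", "ILK", "RIOX2",
    "NT5E", "CCR2", "THY1",
    "TIMP1", "MMP2", "EGFR",
    "CD81", "CD63", "TSG101",
    "EPCAM", "CD44", "CD147", "ERBB2",
)

# Fixed internal seed for the deterministic tag vocabulary; this is part of
# the panel definition, not an experiment seed.
_TAG_VOCABULARY_SEED = 190537


class PanelError(ValueError):
    """Raised when a panel or layout definition violates its invariants."""


@dataclass(frozen=True)
class PanelDefinition:
    """Mapping of antibody names to DNA protein-tag sequences.

    Invariants: at least two entries, all tags unique, equal length, and
    drawn from the {A,C,G,T} alphabet.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise PanelError("panel needs at least 2 antibodies")
        tags = [t for _, t in self.entries]
        names = [n for n, _ in self.entries]
        if len(set(tags)) != len(tags):
            raise PanelError("protein tags must be unique")
        if len(set(names)) != len(names):
            raise PanelError("antibody names must be unique")
        length = len(tags[0])
        for tag in tags:
            if len(tag) != length:
                raise PanelError("all protein tags must have the same length")
            if any(c not in BASES for c in tag):
                raise PanelError(f"protein tag {tag!r} contains non-ACGT characters")

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def tag_length(self) -> int:
        return len(self.entries[0][1])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.entries)

    def tag_codes(self) -> np.ndarray:
        """Tags as a (size, tag_length) uint8 matrix of base codes 0..3."""
        flat = "".join(self.tags).encode()
        arr = np.frombuffer(flat, dtype=np.uint8).reshape(self.size, self.tag_length)
        codes = np.zeros_like(arr)
        for byte, code in _BASE_TO_CODE.items():
            codes[arr == byte] = code
        return codes

    def min_pairwise_distance(self) -> int:
        codes = self.tag_codes()
        neq = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
        np.fill_diagonal(neq, self.tag_length + 1)
        return int(neq.min())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["antibody_name", "protein_tag"])
            writer.writerows(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelDefinition":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or header[:2] != ["antibody_name", "protein_tag"]:
                raise PanelError(
                    f"{path}: expected header 'antibody_name\\tprotein_tag'"
                )
            entries = tuple((row[0], row[1]) for row in reader if row)
        return cls(entries)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; N matches nothing."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def default_panel(
    n: int = 115, tag_length: int = 8, min_distance: int = 3
) -> PanelDefinition:
    """Deterministic default panel of ``n`` antibodies.

    The first entries carry the study's named surface markers; the remainder
    are filler biomarkers ``BM001``... Tag sequences are generated greedily
    with pairwise Hamming distance >= ``min_distance`` so that single-mismatch
    tag matching is unambiguous for error-free reads.
    """
    names = list(NAMED_MARKERS[:n])
    i = 1
    while len(names) < n:
        names.append(f"BM{i:03d}")
        i += 1
    rng = np.random.default_rng(_TAG_VOCABULARY_SEED)
    accepted: list[np.ndarray] = []
    max_tries = 500_000
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            raise PanelError(
                f"could not place {n} tags of length {tag_length} at distance "
                f">= {min_distance}; increase tag_length"
            )
        cand = rng.integers(0, 4, size=tag_length, dtype=np.uint8)
        if all(int((cand != t).sum()) >= min_distance for t in accepted):
            accepted.append(cand)
    entries = tuple(
        (name, "".join(BASES[c] for c in codes))
        for name, codes in zip(names, accepted)
    )
    return PanelDefinition(entries)


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the barcode fields within a read.

    All spans are 0-based half-open ``(start, stop)`` offsets.  The default
    layout is ``[protein_tag 8][UMI 10][anchor 12][exosome_tag 15]`` padded to
    75 nt; the true PBA oligo structure is configurable because assay dialects
    differ.
    """

    protein_tag: tuple[int, int] = (0, 8)
    umi: tuple[int, int] = (8, 18)
    anchor: tuple[int, int] = (18, 30)
    exosome_tag: tuple[int, int] = (30, 45)
    read_length: int = 75
    anchor_seq: str = "ACGTCTGCGATG"

    def __post_init__(self) -> None:
        spans = {
            "protein_tag": self.protein_tag,
            "umi": self.umi,
            "anchor": self.anchor,
            "exosome_tag": self.exosome_tag,
        }
        for name, (start, stop) in spans.items():
            if not (0 <= start < stop <= self.read_length):
                raise PanelError(f"{name} span {start, stop} outside read of "
                                 f"length {self.read_length}")
        ordered = sorted(spans.values())
        for (_, stop), (start, _) in zip(ordered, ordered[1:]):
            if start < stop:
                raise PanelError("layout spans overlap")
        if self.umi[1] - self.umi[0] < 6:
            raise PanelError("UMI must be at least 6 nt")
        if self.exosome_tag[1] - self.exosome_tag[0] < 10:
            raise PanelError("exosome tag must be at least 10 nt")
        if len(self.anchor_seq) != self.anchor[1] - self.anchor[0]:
            raise PanelError("anchor_seq length must match anchor span")

    @property
    def umi_length(self) -> int:
        return self.umi[1] - self.umi[0]

    @property
    def exosome_tag_length(self) -> int:
        return self.exosome_tag[1] - self.exosome_tag[0]

    @property
    def min_parse_length(self) -> int:
        """Minimum read length from which all fields can be sliced."""
        return max(s for _, s in (self.protein_tag, self.umi, self.anchor,
                                  self.exosome_tag))
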
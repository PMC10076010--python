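"""From FASTQ reads to a deduplicated single-exosome protein-count matrix.

Processing funnel: quality filter (a read survives iff *more than* 75% of its
bases reach Q20), field extraction at the configured layout offsets, protein
tag matching against the antibody panel (exact, else unique single-mismatch),
directional UMI deduplication within each (exosome tag, antibody) group, and
assembly into a sparse exosome x protein molecule-count matrix with QC
metrics.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.io import mmread, mmwrite

from .panel import PanelDefinition, ReadLayout

AMBIGUOUS = -1


class FastqFormatError(ValueError):
    """Malformed FASTQ input, reported with the offending record index."""


@dataclass(frozen=True)
class ParsedRecord:
    """Barcode fields sliced out of one surviving read."""

    protein_tag: str
    umi: str
    exosome_tag: str
    quality_pass: bool = True


@dataclass(frozen=True)
class MoleculeRecord:
    """One surviving read resolved to an antibody: the pre-dedup unit."""

    exosome_tag: str
    antibody_id: int
    umi: str


@dataclass
class QcMetrics:
    """Stage-by-stage read funnel counters and matrix summaries."""

    n_reads_in: int = 0
    n_reads_pass_quality: int = 0
    n_parsed: int = 0
    n_matched: int = 0
    n_exosomes: int = 0
    n_molecules: int = 0
    mean_proteins_per_exosome: float = 0.0

    def validate(self) -> None:
        funnel = (self.n_reads_in, self.n_reads_pass_quality, self.n_parsed,
                  self.n_matched)
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise ValueError(f"QC funnel not monotone: {funnel}")
        if self.n_molecules > self.n_matched:
            raise ValueError("more molecules than matched reads")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


@dataclass
class ExosomeProteinMatrix:
    """Sparse single-exosome x protein molecule-count matrix for one sample."""

    exosome_tags: list[str]
    protein_names: list[str]
    counts: sp.csr_matrix
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.exosome_tags), len(self.protein_names)):
            raise ValueError("matrix shape does not match tag/protein labels")

    @property
    def n_exosomes(self) -> int:
        return self.counts.shape[0]

    def proteins_per_exosome(self) -> np.ndarray:
        return np.diff(self.counts.indptr)

    def triplets(self) -> list[tuple[str, str, int]]:
        """Sorted (exosome_tag, protein, count) triplets — the canonical form."""
        coo = self.counts.tocoo()
        return sorted(
            (self.exosome_tags[i], self.protein_names[j], int(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        )

    def save(self, outdir: str | Path, prefix: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix if prefix is not None else self.sample_id
        mmwrite(str(outdir / f"{prefix}.mtx"), self.counts.tocoo())
        (outdir / f"{prefix}.exosomes.tsv").write_text(
            "".join(f"{t}\n" for t in self.exosome_tags)
        )
        (outdir / "proteins.tsv").write_text(
            "".join(f"{p}\n" for p in self.protein_names)
        )

    @classmethod
    def load(cls, outdir: str | Path, prefix: str) -> "ExosomeProteinMatrix":
        outdir = Path(outdir)
        counts = sp.csr_matrix(mmread(str(outdir / f"{prefix}.mtx")))
        tags = (outdir / f"{prefix}.exosomes.tsv").read_text().split()
        proteins = (outdir / "proteins.tsv").read_text().split()
        return cls(tags, proteins, counts, sample_id=prefix)


# -- FASTQ input ---------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples, flagging malformed records."""
    index = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {index}: {exc}"
                ) from exc
            index += 1
            yield rec


# -- quality filter ------------------------------------------------------


def quality_passes(quality: str, min_q: int = 20, min_fraction: float = 0.75) -> bool:
    """True iff the fraction of bases at or above ``min_q`` *exceeds*
    ``min_fraction`` (strict, per the 'more than 75%' rule)."""
    if not quality:
        return False
    low = bytes(range(33, 33 + min_q))
    qb = quality.encode()
    n_hi = len(qb.translate(None, low))
    return n_hi > min_fraction * len(qb)


def quality_filter(
    records: Iterable[tuple[str, str, str]],
    min_q: int = 20,
    min_fraction: float = 0.75,
) -> tuple[list[tuple[str, str, str]], int]:
    """Filter records, preserving order; returns (survivors, n_in)."""
    low = bytes(range(33, 33 + min_q))
    survivors = []
    n_in = 0
    for rec in records:
        n_in += 1
        qb = rec[2].encode()
        if qb and len(qb.translate(None, low)) > min_fraction * len(qb):
            survivors.append(rec)
    return survivors, n_in


# -- field extraction ----------------------------------------------------


def parse_read(seq: str, layout: ReadLayout) -> ParsedRecord | None:
    """Slice barcode fields from a read; None if unparseable.

    Rejected when the read is shorter than the layout span or when the UMI or
    exosome tag contains N (molecule/exosome identity must be exact; N in the
    protein tag is allowed and treated as a mismatch during matching).
    """
    if len(seq) < layout.min_parse_length:
        return None
    umi = seq[layout.umi[0]:layout.umi[1]]
    etag = seq[layout.exosome_tag[0]:layout.exosome_tag[1]]
    if "N" in umi or "N" in etag:
        return None
    return ParsedRecord(
        protein_tag=seq[layout.protein_tag[0]:layout.protein_tag[1]],
        umi=umi,
        exosome_tag=etag,
    )


# -- protein tag matching ------------------------------------------------


class TagMatcher:
    """Resolve protein tags to panel indices with bounded-mismatch tolerance.

    Exact matches win; otherwise a *unique* panel entry within Hamming
    distance <= ``max_mismatch`` wins; ties and no-hits are rejected (None).
    N counts as a mismatch against every base.
    """

    def __init__(self, panel: PanelDefinition, max_mismatch: int = 1):
        self.panel = panel
        self.max_mismatch = max_mismatch
        self.tag_length = panel.tag_length
        self._exact = {tag: i for i, tag in enumerate(panel.tags)}
        self._one_off: dict[str, int] = {}
        if max_mismatch >= 1:
            for i, tag in enumerate(panel.tags):
                for pos in range(len(tag)):
                    for base in "ACGT":
                        if base == tag[pos]:
                            continue
                        mutated = tag[:pos] + base + tag[pos + 1:]
                        if mutated in self._exact:
                            continue  # exact match takes precedence
                        if mutated in self._one_off and self._one_off[mutated] != i:
                            self._one_off[mutated] = AMBIGUOUS
                        else:
                            self._one_off[mutated] = i
        self._tag_bytes = np.frombuffer(
            "".join(panel.tags).encode(), dtype=np.uint8
        ).reshape(panel.size, self.tag_length)

    def match(self, tag: str) -> int | None:
        if len(tag) != self.tag_length:
            raise ValueError(
                f"tag length {len(tag)} != panel tag length {self.tag_length}"
            )
        hit = self._exact.get(tag)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return None
        if self.max_mismatch == 1 and "N" not in tag:
            hit = self._one_off.get(tag)
            return None if hit is None or hit == AMBIGUOUS else hit
        # generic path: full Hamming scan (N never matches)
        qb = np.frombuffer(tag.encode(), dtype=np.uint8)
        dist = (self._tag_bytes != qb).sum(axis=1)
        dmin = int(dist.min())
        if dmin > self.max_mismatch:
            return None
        winners = np.flatnonzero(dist == dmin)
        return int(winners[0]) if winners.size == 1 else None


def match_protein_tag(
    tag: str, panel: PanelDefinition, max_mismatch: int = 1
) -> int | None:
    """Functional wrapper around :class:`TagMatcher` for one-off lookups."""
    return TagMatcher(panel, max_mismatch=max_mismatch).match(tag)


# -- UMI deduplication ---------------------------------------------------


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def directional_roots(counts: Counter) -> list[str]:
    """Root UMIs under the directional network rule.

    UMIs sorted by (count desc, lexicographic); UMI ``u`` absorbs ``v`` when
    Hamming(u, v) <= 1 and count(u) >= 2 * count(v) - 1, traversed
    transitively from each unvisited root in sort order.  Each root stands
    for one original molecule.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    roots: list[str] = []
    for u in order:
        if u in visited:
            continue
        roots.append(u)
        stack = [u]
        visited.add(u)
        while stack:
            x = stack.pop()
            cx = counts[x]
            for v in order:
                if v in visited:
                    continue
                if cx >= 2 * counts[v] - 1 and _hamming1(x, v):
                    visited.add(v)
                    stack.append(v)
    return roots


def directional_components(counts: Counter) -> int:
    """Number of unique molecules under the directional rule."""
    if len(counts) == 1:
        return 1
    return len(directional_roots(counts))


def collapse_umis(
    records: Iterable[MoleculeRecord], method: str = "directional"
) -> dict[tuple[str, int], int]:
    """Deduplicate molecule records to unique molecule counts.

    Records are grouped by (exosome_tag, antibody_id).  ``exact`` counts
    distinct UMIs per group; ``directional`` collapses single-substitution
    UMI errors with the count >= 2*child - 1 rule.  Returns the molecule
    count per group.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown UMI collapse method {method!r}")
    groups: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for rec in records:
        groups[(rec.exosome_tag, rec.antibody_id)][rec.umi] += 1
    if method == "exact":
        return {key: len(c) for key, c in groups.items()}
    return {key: directional_components(c) for key, c in groups.items()}


def collapse_exosome_tags(
    records: Sequence[MoleculeRecord],
) -> list[MoleculeRecord]:
    """Optional frequency-based Hamming-1 collapse of exosome tags.

    A tag is absorbed into a neighboring tag (Hamming distance 1) with read
    count >= 2 * its own - 1, preferring the most frequent neighbor.  Off by
    default in the pipeline: exosome tags are arbitrary extension products
    with no whitelist, and merging risks fusing true exosomes.
    """
    tag_counts = Counter(r.exosome_tag for r in records)
    order = sorted(tag_counts, key=lambda t: (-tag_counts[t], t))
    rank = {t: i for i, t in enumerate(order)}
    mapping: dict[str, str] = {}
    for tag in reversed(order):  # least frequent first
        best: str | None = None
        for pos in range(len(tag)):
            for base in "ACGT":
                if base == tag[pos]:
                    continue
                neighbor = tag[:pos] + base + tag[pos + 1:]
                cnt = tag_counts.get(neighbor)
                if cnt is None or cnt < 2 * tag_counts[tag] - 1:
                    continue
                if rank[neighbor] >= rank[tag]:
                    continue
                if best is None or rank[neighbor] < rank[best]:
                    best = neighbor
        if best is not None:
            mapping[tag] = mapping.get(best, best)
    if not mapping:
        return list(records)
    return [
        MoleculeRecord(mapping.get(r.exosome_tag, r.exosome_tag),
                       r.antibody_id, r.umi)
        for r in records
    ]


# -- matrix assembly -----------------------------------------------------


def build_matrix(
    molecule_counts: dict[tuple[str, int], int],
    panel: PanelDefinition,
    sample_id: str = "",
) -> ExosomeProteinMatrix:
    """Assemble deduplicated molecule counts into a sparse matrix.

    Rows are distinct exosome tags (lexicographically sorted for
    reproducibility), columns follow panel order.
    """
    tags = sorted({tag for tag, _ in molecule_counts})
    tag_index = {t: i for i, t in enumerate(tags)}
    rows, cols, data = [], [], []
    for (tag, aid), count in molecule_counts.items():
        rows.append(tag_index[tag])
        cols.append(aid)
        data.append(count)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(tags), panel.size), dtype=np.int64
    )
    return ExosomeProteinMatrix(tags, list(panel.names), counts, sample_id)


def qc_metrics(
    matrix: ExosomeProteinMatrix,
    n_reads_in: int,
    n_reads_pass_quality: int,
    n_parsed: int,
    n_matched: int,
) -> QcMetrics:
    """Assemble funnel counters and matrix summaries; validates monotonicity."""
    ppe = matrix.proteins_per_exosome()
    qc = QcMetrics(
        n_reads_in=n_reads_in,
        n_reads_pass_quality=n_reads_pass_quality,
        n_parsed=n_parsed,
        n_matched=n_matched,
        n_exosomes=matrix.n_exosomes,
        n_molecules=int(matrix.counts.sum()),
        mean_proteins_per_exosome=float(ppe.mean()) if ppe.size else 0.0,
    )
    qc.validate()
    return qc


# -- one-sample pipeline -------------------------------------------------


def process_fastq(
    fastq_path: str | Path,
    panel: PanelDefinition,
    layout: ReadLayout | None = None,
    sample_id: str | None = None,
    min_q: int = 20,
    min_fraction: float = 0.75,
    max_mismatch: int = 1,
    umi_method: str = "directional",
    collapse_tags: bool = False,
) -> tuple[ExosomeProteinMatrix, QcMetrics]:
    """Run the full funnel for one sample's FASTQ file."""
    layout = layout or ReadLayout()
    if sample_id is None:
        sample_id = Path(fastq_path).stem
    matcher = TagMatcher(panel, max_mismatch=max_mismatch)
    low = bytes(range(33, 33 + min_q))

    n_in = n_quality = n_parsed = n_matched = 0
    records: list[MoleculeRecord] = []
    for _, seq, qual in read_fastq(fastq_path):
        n_in += 1
        qb = qual.encode()
        if not qb or len(qb.translate(None, low)) <= min_fraction * len(qb):
            continue
        n_quality += 1
        parsed = parse_read(seq, layout)
        if parsed is None:
            continue
        n_parsed += 1
        aid = matcher.match(parsed.protein_tag)
        if aid is None:
            continue
        n_matched += 1
        records.append(MoleculeRecord(parsed.exosome_tag, aid, parsed.umi))

    if collapse_tags:
        records = collapse_exosome_tags(records)
    molecules = collapse_umis(records, method=umi_method)
    matrix = build_matrix(molecules, panel, sample_id=sample_id)
    qc = qc_metrics(matrix, n_in, n_quality, n_parsed, n_matched)
    return matrix, qc
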
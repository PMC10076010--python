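"""Synthetic single-exosome PBA data: ground-truth profiles and FASTQ reads.

The generative model per exosome: a subpopulation label drawn from the
group's mixing proportions; a molecule count ``m ~ 1 + Poisson(mean - 1)``
(a detected exosome carries at least one molecule); and ``m`` *distinct*
proteins drawn without replacement with probabilities proportional to the
subpopulation's signature weights.  Proteins are drawn without replacement so
that the number of deduplicated molecules on an exosome equals the number of
distinct proteins detected on it — the quantity the assay reports (the study
detects on average 2.4 proteins per exosome, and its molecule/exosome totals
give the same ratio).

Read emission renders each molecule as ``1 + Poisson(duplication_rate)``
sequenced copies carrying the molecule's UMI and its exosome's tag, applies
per-base substitution errors, and assigns a two-state quality model: good
reads are uniformly Q37, while a fixed fraction of reads receive >25% of
bases below Q20 and are thereby guaranteed to fail the downstream quality
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .design import CohortDesign, DesignError
from .panel import BASES, PanelDefinition, ReadLayout

_ASCII_BASES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass
class SampleTruth:
    """Ground truth for one sample: labels and binary molecule counts."""

    sample_id: str
    group: str
    cluster_labels: np.ndarray  # (n_exosomes,) int, 1..K
    counts: sp.csr_matrix  # (n_exosomes, P) molecule counts
    exosome_tags: np.ndarray | None = None  # filled by emit_reads

    @property
    def n_exosomes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_molecules(self) -> int:
        return int(self.counts.sum())


@dataclass
class TruthProfiles:
    """Per-sample ground truth for a simulated cohort."""

    samples: list[SampleTruth]
    protein_names: tuple[str, ...]
    n_clusters: int

    def sample(self, sample_id: str) -> SampleTruth:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def simulate_truth(design: CohortDesign, seed: int) -> TruthProfiles:
    """Draw ground-truth single-exosome profiles for every sample.

    Reproducible under ``seed``; raises :class:`DesignError` for an invalid
    design.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    k = design.n_clusters
    p = len(design.protein_names)
    n = design.exosomes_per_sample
    mean_m = design.molecules_per_exosome_mean

    # normalized signature rows and their log for Gumbel top-m sampling
    sig = design.signatures / design.signatures.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        log_sig = np.log(sig)
    support = (sig > 0).sum(axis=1)

    samples: list[SampleTruth] = []
    for group, n_samples in design.groups:
        pi = design.mixing[group]
        for i in range(n_samples):
            sample_id = f"{group}_{i + 1:02d}"
            labels0 = rng.choice(k, size=n, p=pi)  # 0-based
            m = 1 + rng.poisson(mean_m - 1.0, size=n)
            m = np.minimum(m, support[labels0])
            # Gumbel top-m: the m largest of log w_j + G_j are a without-
            # replacement draw with probabilities proportional to w.
            gumbel = rng.gumbel(size=(n, p)) + log_sig[labels0]
            order = np.argsort(-gumbel, axis=1)
            rows = np.repeat(np.arange(n), m)
            take = np.concatenate([order[i, : m[i]] for i in range(n)]) if n else \
                np.empty(0, dtype=int)
            counts = sp.csr_matrix(
                (np.ones(len(rows), dtype=np.int64), (rows, take)), shape=(n, p)
            )
            samples.append(
                SampleTruth(
                    sample_id=sample_id,
                    group=group,
                    cluster_labels=(labels0 + 1).astype(np.int32),
                    counts=counts,
                )
            )
    return TruthProfiles(samples=samples, protein_names=tuple(design.protein_names),
                         n_clusters=k)


def _random_tag_codes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct random tags as base-code rows (uniform over distinct draws)."""
    out = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    # enforce within-sample uniqueness by redrawing collisions
    while True:
        view = np.ascontiguousarray(out).view(
            np.dtype((np.void, out.dtype.itemsize * length))
        ).ravel()
        _, first = np.unique(view, return_index=True)
        dup = np.setdiff1d(np.arange(n), first, assume_unique=False)
        if dup.size == 0:
            return out
        out[dup] = rng.integers(0, 4, size=(dup.size, length), dtype=np.uint8)


def _codes_to_strings(codes: np.ndarray) -> np.ndarray:
    ascii_rows = _ASCII_BASES[codes]
    n, length = codes.shape
    return ascii_rows.view(f"S{length}").ravel().astype(str)


def emit_reads(
    truth: TruthProfiles,
    panel: PanelDefinition,
    layout: ReadLayout,
    design: CohortDesign,
    outdir: str | Path,
    seed: int,
) -> dict[str, Path]:
    """Render truth profiles as error-bearing FASTQ files plus truth sidecars.

    Writes ``<sample>.fastq`` per sample, ``truth_clusters.tsv``
    (exosome_tag, sample_id, cluster_label) and ``truth_counts.tsv``
    (sample_id, exosome_tag, protein, count).  Returns the FASTQ paths keyed
    by sample id, and records each sample's exosome tags on the truth object.
    """
    if panel.size < len(truth.protein_names):
        raise DesignError("panel smaller than the truth's protein space")
    if panel.tag_length != layout.protein_tag[1] - layout.protein_tag[0]:
        raise DesignError("panel tag length does not match layout protein_tag span")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    tag_codes_panel = panel.tag_codes()
    anchor_codes = np.frombuffer(layout.anchor_seq.encode(), dtype=np.uint8).copy()
    for byte, code in zip(b"ACGT", range(4)):
        anchor_codes[anchor_codes == byte] = code
    etag_len = layout.exosome_tag_length
    umi_len = layout.umi_length
    # good reads: all bases at Q37 ('F'); bad reads: 30% of bases at Q2 ('#')
    n_low = int(np.floor(0.30 * layout.read_length))

    fastq_paths: dict[str, Path] = {}
    clusters_path = outdir / "truth_clusters.tsv"
    counts_path = outdir / "truth_counts.tsv"
    with open(clusters_path, "w") as cl_fh, open(counts_path, "w") as ct_fh:
        cl_fh.write("exosome_tag\tsample_id\tcluster_label\n")
        ct_fh.write("sample_id\texosome_tag\tprotein\tcount\n")
        for s in truth.samples:
            n_exo = s.n_exosomes
            etag_codes = _random_tag_codes(rng, n_exo, etag_len)
            etags = _codes_to_strings(etag_codes)
            s.exosome_tags = etags

            coo = s.counts.tocoo()
            mol_exo = np.repeat(coo.row, coo.data)
            mol_prot = np.repeat(coo.col, coo.data)
            n_mol = mol_exo.size
            umi_codes = rng.integers(0, 4, size=(n_mol, umi_len), dtype=np.uint8)
            copies = 1 + rng.poisson(design.duplication_rate, size=n_mol)
            read_mol = np.repeat(np.arange(n_mol), copies)
            n_reads = read_mol.size

            reads = np.zeros((n_reads, layout.read_length), dtype=np.uint8)
            a, b = layout.protein_tag
            reads[:, a:b] = tag_codes_panel[mol_prot[read_mol]]
            a, b = layout.umi
            reads[:, a:b] = umi_codes[read_mol]
            a, b = layout.anchor
            reads[:, a:b] = anchor_codes
            a, b = layout.exosome_tag
            reads[:, a:b] = etag_codes[mol_exo[read_mol]]
            # remaining positions stay base code 0 ('A') as constant padding

            if design.substitution_rate > 0 and n_reads:
                mask = rng.random(reads.shape) < design.substitution_rate
                shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                reads[mask] = (reads[mask] + shifts) % 4

            # two-state quality: exactly round(frac * n) bad reads
            quals = np.full((n_reads, layout.read_length), ord("F"), dtype=np.uint8)
            n_bad = int(round(design.low_quality_read_fraction * n_reads))
            if n_bad:
                bad_idx = rng.choice(n_reads, size=n_bad, replace=False)
                pos = np.argsort(rng.random((n_bad, layout.read_length)),
                                 axis=1)[:, :n_low]
                quals[bad_idx[:, None], pos] = ord("#")  # Q2

            seqs = _ASCII_BASES[reads].view(f"S{layout.read_length}").ravel()
            qstr = quals.view(f"S{layout.read_length}").ravel()
            fastq_path = outdir / f"{s.sample_id}.fastq"
            with open(fastq_path, "w") as fq:
                sid = s.sample_id
                fq.writelines(
                    f"@{sid}:{i}\n{seqs[i].decode()}\n+\n{qstr[i].decode()}\n"
                    for i in range(n_reads)
                )
            fastq_paths[s.sample_id] = fastq_path

            cl_fh.writelines(
                f"{etags[i]}\t{s.sample_id}\t{s.cluster_labels[i]}\n"
                for i in range(n_exo)
            )
            names = truth.protein_names
            ct_fh.writelines(
                f"{s.sample_id}\t{etags[e]}\t{names[p_]}\t{c}\n"
                for e, p_, c in zip(coo.row, coo.col, coo.data)
            )
    return fastq_paths


def simulate_dataset(
    design: CohortDesign,
    outdir: str | Path,
    seed: int,
    panel: PanelDefinition | None = None,
    layout: ReadLayout | None = None,
) -> tuple[TruthProfiles, dict[str, Path]]:
    """Simulate truth and emit reads, panel TSV and sample metadata in one go."""
    from .panel import default_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = default_panel(n=len(design.protein_names))
        if panel.names != tuple(design.protein_names):
            raise DesignError(
                "design protein names do not match the default panel; "
                "pass a matching PanelDefinition"
            )
    if layout is None:
        layout = ReadLayout()
    truth = simulate_truth(design, seed)
    fastq_paths = emit_reads(truth, panel, layout, design, outdir, seed + 1)
    panel.to_tsv(outdir / "panel.tsv")
    with open(outdir / "metadata.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in truth.samples:
            fh.write(f"{s.sample_id}\t{s.group}\n")
    design.to_yaml(outdir / "design.yaml")
    return truth, fastq_paths
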
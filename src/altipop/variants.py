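"""Variant tables, transcript annotation and descriptive SNP statistics.

The central container is :class:`VariantTable`: biallelic SNPs located on
transcriptome contigs, with per-sample diploid genotypes stored as alt-allele
dosage (0/1/2, -1 for missing).  Around it live the descriptive statistics a
transcriptome SNP survey reports: per-population SNP density, the
transition/transversion ratio and the 12-class directed mutation spectrum,
the private/shared (Venn) partition of sites across populations, and the
classification of coding SNPs as synonymous or non-synonymous via the
standard nuclear codon table.

Coordinates are 1-based inclusive in all files (VCF/annotation convention)
and 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MISSING = -1
BASES = ("A", "C", "G", "T")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

__all__ = [
    "VariantTable",
    "TranscriptAnnotation",
    "PopulationDesign",
    "read_vcf",
    "write_vcf",
    "classify_substitution",
    "spectrum_counts",
    "ts_tv_ratio",
    "snp_density",
    "private_shared_sets",
    "classify_coding_effect",
    "coding_effect_table",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantTable:
    """Biallelic SNP records with per-sample alt-allele dosages.

    Attributes
    ----------
    transcript_id : array of str, one entry per site
    pos : array of int, 1-based position within the transcript
    ref, alt : arrays of single bases
    genotypes : int8 array of shape (n_sites, n_samples); dosage in
        {0, 1, 2} or -1 for a missing call
    samples : ordered sample names (columns of ``genotypes``)
    """

    transcript_id: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: List[str]

    def __post_init__(self) -> None:
        self.transcript_id = np.asarray(self.transcript_id, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = list(self.samples)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.pos)
        for arr, name in [(self.transcript_id, "transcript_id"), (self.ref, "ref"), (self.alt, "alt")]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} sites")
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {len(self.samples)})"
            )
        if n:
            for b in np.concatenate([self.ref, self.alt]):
                if b not in BASES:
                    raise ValueError(f"non-ACGT allele {b!r}")
            if np.any(self.ref == self.alt):
                raise ValueError("ref == alt at some site")
            keys = list(zip(self.transcript_id, self.pos))
            if len(set(keys)) != n:
                raise ValueError("duplicate (transcript_id, pos)")
        g = self.genotypes
        if g.size and not np.all(((g >= 0) & (g <= 2)) | (g == MISSING)):
            raise ValueError("genotype dosages must be 0/1/2 or -1 (missing)")

    # -- convenience -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.transcript_id[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.genotypes[mask],
            self.samples,
        )

    def alt_counts(self, sample_idx: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called chromosome count) over samples."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        n_chr = 2 * called.sum(axis=1)
        return alt.astype(np.int64), n_chr.astype(np.int64)

    def segregating_mask(self, sample_idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Sites polymorphic (0 < alt count < called chromosomes) in the subset."""
        alt, n_chr = self.alt_counts(sample_idx)
        return (alt > 0) & (alt < n_chr)

    def present_mask(self, sample_idx: np.ndarray, min_freq: float = 0.0) -> np.ndarray:
        """Sites carrying >=1 alt allele (or alt frequency > min_freq) in the subset."""
        alt, n_chr = self.alt_counts(sample_idx)
        if min_freq > 0.0:
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(n_chr > 0, alt / np.maximum(n_chr, 1), 0.0)
            return freq > min_freq
        return alt > 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"transcript_id": self.transcript_id, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )
        for j, s in enumerate(self.samples):
            df[s] = self.genotypes[:, j]
        return df

    def __eq__(self, other: object) -> bool:  # canonical-table equality
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.transcript_id, other.transcript_id)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class TranscriptAnnotation:
    """Per-transcript structure: length, CDS interval/frame, UTRs, sequence.

    ``table`` columns: transcript_id, length, cds_start, cds_end, frame,
    utr5_start, utr5_end, utr3_start, utr3_end, covered_bp.  Interval columns
    are 1-based inclusive; absent intervals are 0.  ``sequences`` optionally
    maps transcript_id -> reference sequence (needed for codon translation).
    """

    table: pd.DataFrame
    sequences: Optional[Dict[str, str]] = None

    _COLS = [
        "transcript_id", "length", "cds_start", "cds_end", "frame",
        "utr5_start", "utr5_end", "utr3_start", "utr3_end", "covered_bp",
    ]

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self._COLS if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        bad = t[(t.cds_start > 0) & (t.cds_end - t.cds_start + 1 < 3)]
        if len(bad):
            raise ValueError("CDS shorter than one codon for " + ", ".join(bad.transcript_id))
        for lo, hi in [("cds_start", "cds_end"), ("utr5_start", "utr5_end"), ("utr3_start", "utr3_end")]:
            present = t[lo] > 0
            if np.any(present & ((t.loc[present, lo] < 1) | (t.loc[present, hi] > t.loc[present, "length"]))):
                raise ValueError(f"interval {lo}/{hi} outside [1, length]")
        self._by_id = t.set_index("transcript_id", drop=False)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.table.transcript_id)

    def row(self, transcript_id: str) -> pd.Series:
        return self._by_id.loc[transcript_id]

    def total_covered_bp(self) -> int:
        return int(self.table.covered_bp.sum())

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        self.table[self._COLS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, fasta: Optional[str] = None) -> "TranscriptAnnotation":
        table = pd.read_csv(path, sep="\t")
        sequences = None
        if fasta is not None:
            from Bio import SeqIO

            sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta, "fasta")}
        return cls(table, sequences)

    def write_fasta(self, path: str) -> None:
        if self.sequences is None:
            raise ValueError("annotation carries no sequences")
        with open(path, "w") as fh:
            for tid in self.transcript_ids:
                fh.write(f">{tid}\n")
                seq = self.sequences[tid]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass
class PopulationDesign:
    """Ordered population labels and the sample -> population assignment."""

    labels: Tuple[str, ...]
    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        extra = set(self.assignment.values()) - set(self.labels)
        if extra:
            raise ValueError(f"samples assigned to unknown populations {sorted(extra)}")

    def samples_for(self, label: str) -> List[str]:
        return [s for s, p in self.assignment.items() if p == label]

    def require_min_samples(self, k: int = 2) -> None:
        for lab in self.labels:
            n = len(self.samples_for(lab))
            if n < k:
                raise ValueError(f"population {lab} has {n} samples; >= {k} required")

    def indices(self, table: VariantTable) -> Dict[str, np.ndarray]:
        return {lab: table.sample_index(self.samples_for(lab)) for lab in self.labels}

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"sample": list(self.assignment), "population": [self.assignment[s] for s in self.assignment]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, labels: Optional[Sequence[str]] = None) -> "PopulationDesign":
        df = pd.read_csv(path, sep="\t")
        assignment = dict(zip(df["sample"], df["population"]))
        if labels is None:
            labels = list(dict.fromkeys(df["population"]))
        return cls(tuple(labels), assignment)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def write_vcf(table: VariantTable, path: str, contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write the table as VCF 4.2 with a GT FORMAT field."""
    header = pysam.VariantHeader()
    header.add_meta("source", "altipop")
    contigs: Dict[str, int] = {}
    if contig_lengths:
        contigs.update({k: int(v) for k, v in contig_lengths.items()})
    for tid, pos in zip(table.transcript_id, table.pos):
        contigs[tid] = max(contigs.get(tid, 0), int(pos))
    for tid, length in contigs.items():
        header.contigs.add(tid, length=length)
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")]
    )
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(table.n_sites):
            rec = out.new_record(
                contig=str(table.transcript_id[i]),
                start=int(table.pos[i]) - 1,
                alleles=(str(table.ref[i]), str(table.alt[i])),
            )
            for j, s in enumerate(table.samples):
                d = table.genotypes[i, j]
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 1) if d == 1 else ((1, 1) if d == 2 else (0, 0))
            out.write(rec)


def read_vcf(path: str) -> Tuple[VariantTable, int]:
    """Read a VCF into a VariantTable.

    Non-biallelic-SNP records are skipped; the skip count is returned and
    logged.  Raises if the file declares no GT FORMAT.
    """
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF lacks a GT FORMAT field")
        samples = list(vcf.header.samples)
        tids: List[str] = []
        poss: List[int] = []
        refs: List[str] = []
        alts: List[str] = []
        rows: List[List[int]] = []
        skipped = 0
        for rec in vcf:
            alleles = rec.alleles
            if (
                alleles is None
                or len(alleles) != 2
                or any(len(a) != 1 or a not in BASES for a in alleles)
            ):
                skipped += 1
                continue
            tids.append(rec.contig)
            poss.append(rec.pos)
            refs.append(alleles[0])
            alts.append(alleles[1])
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(MISSING)
                else:
                    row.append(int(sum(1 for a in gt if a != 0)))
            rows.append(row)
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, skipped)
    genotypes = np.asarray(rows, dtype=np.int8).reshape(len(tids), len(samples))
    table = VariantTable(
        np.asarray(tids, dtype=object),
        np.asarray(poss),
        np.asarray(refs, dtype=object),
        np.asarray(alts, dtype=object),
        genotypes,
        samples,
    )
    return table, skipped


# ---------------------------------------------------------------------------
# substitution classes and spectrum


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else 'transversion'."""
    for b in (ref, alt):
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    pair = {ref, alt}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def spectrum_counts(
    table: VariantTable,
    design: Optional[PopulationDesign] = None,
) -> pd.DataFrame:
    """Directed 12-class mutation spectrum (ref->alt counts).

    With a design, one column per population counts only sites segregating
    within that population; otherwise a single 'all' column over all sites.
    """
    classes = [f"{r}>{a}" for r in BASES for a in BASES if r != a]
    key = np.array([f"{r}>{a}" for r, a in zip(table.ref, table.alt)], dtype=object)
    cols: Dict[str, np.ndarray] = {}
    if design is None:
        masks = {"all": np.ones(table.n_sites, dtype=bool)}
    else:
        idx = design.indices(table)
        masks = {lab: table.segregating_mask(idx[lab]) for lab in design.labels}
    for lab, mask in masks.items():
        sub = key[mask]
        cols[lab] = np.array([int(np.sum(sub == c)) for c in classes])
    return pd.DataFrame(cols, index=pd.Index(classes, name="substitution"))


def ts_tv_ratio(table: VariantTable) -> float:
    """Transition/transversion count ratio over all sites (inf if no transversions)."""
    kinds = [classify_substitution(r, a) for r, a in zip(table.ref, table.alt)]
    ts = sum(k == "transition" for k in kinds)
    tv = len(kinds) - ts
    return float("inf") if tv == 0 else ts / tv


# ---------------------------------------------------------------------------
# densities and Venn partition


def snp_density(
    table: VariantTable,
    design: PopulationDesign,
    annotation: TranscriptAnnotation,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Per-population SNP density in SNPs/Mb.

    Default mode counts sites segregating within the population sample and
    divides by covered Mb.  ``per_sample=True`` instead counts heterozygous-
    or-alt sites per individual and reports mean and sd across the
    population's individuals (the 'x ± y /Mb' presentation).
    """
    covered = annotation.total_covered_bp()
    if covered <= 0:
        raise ValueError("total covered length is zero")
    mb = covered / 1e6
    idx = design.indices(table)
    rows = []
    for lab in design.labels:
        if per_sample:
            g = table.genotypes[:, idx[lab]]
            per_ind = ((g == 1) | (g == 2)).sum(axis=0) / mb
            rows.append(
                {"population": lab, "density_per_mb": float(per_ind.mean()),
                 "density_sd": float(per_ind.std(ddof=1)) if len(per_ind) > 1 else float("nan"),
                 "n_snps": float(per_ind.mean() * mb), "covered_mb": mb}
            )
        else:
            n = int(table.segregating_mask(idx[lab]).sum())
            rows.append(
                {"population": lab, "density_per_mb": n / mb, "density_sd": float("nan"),
                 "n_snps": n, "covered_mb": mb}
            )
    return pd.DataFrame(rows)


def private_shared_sets(
    table: VariantTable, design: PopulationDesign, min_freq: float = 0.0
) -> Dict[str, int]:
    """Venn-region site counts over populations.

    A site is *present* in a population iff it carries >= 1 alt allele there
    (configurable to an alt-frequency threshold).  Keys are sorted '+'-joined
    label combinations, e.g. 'H', 'L+M', 'H+L+M'; sites present nowhere are
    counted under 'none'.
    """
    idx = design.indices(table)
    present = {lab: table.present_mask(idx[lab], min_freq=min_freq) for lab in design.labels}
    counts: Dict[str, int] = {}
    stack = np.column_stack([present[lab] for lab in design.labels])
    for row in stack:
        labs = [lab for lab, p in zip(design.labels, row) if p]
        key = "+".join(sorted(labs)) if labs else "none"
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# coding-effect classification

_EFFECTS = ("synonymous", "non-synonymous", "utr5", "utr3", "noncoding")


def classify_coding_effect(
    transcript_id: str,
    pos: int,
    ref: str,
    alt: str,
    annotation: TranscriptAnnotation,
) -> Tuple[str, bool]:
    """Classify a SNP as synonymous / non-synonymous / utr5 / utr3 / noncoding.

    Returns ``(effect, stop_involved)``; *stop_involved* flags stop gain or
    loss (reported as non-synonymous).  Positions are 1-based.  Bases of a
    CDS codon other than the SNP come from the annotation's reference
    sequence.  CDS tails shorter than a full codon are treated as noncoding.
    """
    ann = annotation.row(transcript_id)
    if ann.utr5_start > 0 and ann.utr5_start <= pos <= ann.utr5_end:
        return "utr5", False
    if ann.utr3_start > 0 and ann.utr3_start <= pos <= ann.utr3_end:
        return "utr3", False
    if not (ann.cds_start > 0 and ann.cds_start <= pos <= ann.cds_end):
        return "noncoding", False
    cds_len = int(ann.cds_end - ann.cds_start + 1) - int(ann.frame)
    if cds_len % 3 != 0:
        logger.warning(
            "transcript %s: CDS length %d not divisible by 3; trailing bases noncoding",
            transcript_id, cds_len,
        )
    offset = int(pos - ann.cds_start - ann.frame)
    if offset < 0 or offset >= 3 * (cds_len // 3):
        return "noncoding", False  # inside frame-shift head or trailing partial codon
    if annotation.sequences is None:
        raise ValueError("coding classification requires reference sequences (FASTA)")
    seq = annotation.sequences[transcript_id]
    codon_idx = offset // 3
    codon_start0 = int(ann.cds_start) - 1 + int(ann.frame) + 3 * codon_idx
    codon = list(seq[codon_start0 : codon_start0 + 3])
    within = offset % 3
    if codon[within] != ref:
        logger.warning(
            "transcript %s pos %d: reference sequence %s != ref allele %s; using ref allele",
            transcript_id, pos, codon[within], ref,
        )
    ref_codon = codon.copy()
    ref_codon[within] = ref
    alt_codon = codon.copy()
    alt_codon[within] = alt
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    stop = (aa_ref == "*") != (aa_alt == "*")
    return ("synonymous" if aa_ref == aa_alt else "non-synonymous"), stop


def coding_effect_table(
    table: VariantTable,
    annotation: TranscriptAnnotation,
    design: Optional[PopulationDesign] = None,
) -> pd.DataFrame:
    """Per-site effect classes; with a design, per-population effect counts too."""
    effects = []
    stops = []
    for tid, pos, ref, alt in zip(table.transcript_id, table.pos, table.ref, table.alt):
        e, s = classify_coding_effect(str(tid), int(pos), str(ref), str(alt), annotation)
        effects.append(e)
        stops.append(s)
    df = table.to_dataframe()[["transcript_id", "pos", "ref", "alt"]]
    df["effect"] = effects
    df["stop_involved"] = stops
    if design is not None:
        idx = design.indices(table)
        for lab in design.labels:
            df[f"segregating_{lab}"] = table.segregating_mask(idx[lab])
    return df
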
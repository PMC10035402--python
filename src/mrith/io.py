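"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* Cohort table: TSV in the 10-column clinical layout
  (``Indiv Type Hpy Ctry Eth Sex Age Hist Anat Stage``) with ``NA`` for
  missing cells and abbreviated category tokens; ``Subtotal``/``Total``
  rows are skipped on read.
* Variant tables: MAF-like TSV (one variant-biopsy row) or a minimal
  multi-sample VCF 4.2 with AD/DP FORMAT fields (read via pysam).
* CNV segments, microsatellite repeat-length histograms, EBV read
  fractions, signature catalogs: plain TSV.
* Trees: Newick.

Coordinate conventions: variants are 1-based (VCF convention); panel BED
intervals are half-open 0-based.  Variant identity everywhere is the
normalized key ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .phylogeny import ClonalTree
    from .subtyping import CNVSegment, MSILocus


class ParseError(ValueError):
    """A file could not be interpreted in its declared format."""


class ValidationError(ValueError):
    """A record violates an invariant of its domain type."""


SUBTYPES = ("EBV", "MSI", "CIN", "GS")
EFFECTS = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "inframe_indel",
    "silent",
    "other",
)
NA = "NA"  # the missingness token, case-sensitive

_STAGE_RE = re.compile(r"^(IV|III|II|I)")

# clinical-table abbreviation maps (file token -> stored value)
_COUNTRY = {"Col": "Colombia", "Mex": "Mexico", "USA": "USA"}
_ETHNICITY = {"Lat": "Latino", "Wht": "White"}
_HISTOLOGY = {"I": "intestinal", "D": "diffuse", "M": "mixed"}
_HPYLORI = {"Y": "yes", "N": "no"}
_COUNTRY_INV = {v: k for k, v in _COUNTRY.items()}
_ETHNICITY_INV = {v: k for k, v in _ETHNICITY.items()}
_HISTOLOGY_INV = {v: k for k, v in _HISTOLOGY.items()}
_HPYLORI_INV = {v: k for k, v in _HPYLORI.items()}

COHORT_COLUMNS = (
    "Indiv", "Type", "Hpy", "Ctry", "Eth", "Sex", "Age", "Hist", "Anat", "Stage",
)


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical cohort table.

    Missing values are ``None`` (written/read as the token ``NA``).
    """

    patient_id: str
    subtype_assigned: str | None = None
    hpylori: str | None = None       # "yes" / "no"
    country: str | None = None       # Colombia / Mexico / USA
    ethnicity: str | None = None     # Latino / White
    sex: str | None = None           # M / F
    age: int | None = None
    histology: str | None = None     # intestinal / diffuse / mixed
    anatomic_site: str | None = None
    stage: str | None = None         # AJCC-style, begins with I/II/III/IV

    def __post_init__(self) -> None:
        if self.subtype_assigned is not None and self.subtype_assigned not in SUBTYPES:
            raise ValidationError(
                f"{self.patient_id}: unknown subtype {self.subtype_assigned!r}"
            )
        if self.age is not None and not (0 <= self.age <= 120):
            raise ValidationError(f"{self.patient_id}: age {self.age} out of [0,120]")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.stage is not None and not _STAGE_RE.match(self.stage):
            raise ValidationError(f"{self.patient_id}: malformed stage {self.stage!r}")


@dataclass(frozen=True)
class VariantCall:
    """A somatic SNV/indel observed (or force-called) in one tumor biopsy."""

    biopsy_id: str
    patient_id: str
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    alt_reads: int
    depth: int
    gene: str | None = None
    effect: str | None = None
    trinucleotide_context: str | None = None
    called: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} < 1")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.depth <= 0:
            raise ValidationError(f"non-positive depth {self.depth} at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValidationError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.effect is not None and self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class PanelDefinition:
    """Capture-panel geometry: target intervals plus per-gene CDS lengths."""

    target_regions: tuple[tuple[str, int, int], ...]
    gene_cds_kbp: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, start, end in self.target_regions:
            if end < start or start < 0:
                raise ValidationError(f"bad interval {chrom}:{start}-{end}")
        for g, l in self.gene_cds_kbp.items():
            if l <= 0:
                raise ValidationError(f"non-positive CDS length for {g}")
        if self.target_bases <= 0:
            raise ValidationError("panel has zero target bases")

    @property
    def target_bases(self) -> int:
        return sum(e - s for _, s, e in self.target_regions)

    @property
    def target_mbp(self) -> float:
        return self.target_bases / 1e6


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def _expand(token: str, table: Mapping[str, str], row: int, col: str) -> str | None:
    if token == NA:
        return None
    if token not in table:
        raise ParseError(f"row {row}, column {col}: unknown token {token!r}")
    return table[token]


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a clinical cohort TSV into :class:`PatientRecord` objects.

    ``Subtotal``/``Total`` layout rows are skipped; ``NA`` cells become
    ``None``.  Raises :class:`ParseError` on an empty file, a bad header, or
    an unrecognized category token (naming row and column).
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty cohort table") from None
        header = [h.strip() for h in header]
        if header[: len(COHORT_COLUMNS)] != list(COHORT_COLUMNS):
            raise ParseError(
                f"{path}: header {header!r} does not match {COHORT_COLUMNS!r}"
            )
        records: list[PatientRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            indiv = row[0].strip()
            if indiv in ("Subtotal", "Total"):
                continue
            row = [c.strip() for c in row] + [""] * (len(COHORT_COLUMNS) - len(row))
            if indiv in seen:
                raise ParseError(f"row {i}: duplicate patient_id {indiv!r}")
            seen.add(indiv)
            subtype = None if row[1] == NA else row[1]
            if subtype is not None and subtype not in SUBTYPES:
                raise ParseError(f"row {i}, column Type: unknown token {row[1]!r}")
            sex = None if row[5] == NA else row[5]
            if sex is not None and sex not in ("M", "F"):
                raise ParseError(f"row {i}, column Sex: unknown token {row[5]!r}")
            try:
                age = None if row[6] == NA else int(row[6])
            except ValueError:
                raise ParseError(f"row {i}, column Age: not an integer: {row[6]!r}") from None
            records.append(
                PatientRecord(
                    patient_id=indiv,
                    subtype_assigned=subtype,
                    hpylori=_expand(row[2], _HPYLORI, i, "Hpy"),
                    country=_expand(row[3], _COUNTRY, i, "Ctry"),
                    ethnicity=_expand(row[4], _ETHNICITY, i, "Eth"),
                    sex=sex,
                    age=age,
                    histology=_expand(row[7], _HISTOLOGY, i, "Hist"),
                    anatomic_site=None if row[8] in (NA, "") else row[8],
                    stage=None if row[9] in (NA, "") else row[9],
                )
            )
    return records


def write_cohort_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patients back out in the abbreviated 10-column layout."""
    def tok(value: str | None, inv: Mapping[str, str] | None = None) -> str:
        if value is None:
            return NA
        return inv[value] if inv else str(value)

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COHORT_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id,
                tok(r.subtype_assigned),
                tok(r.hpylori, _HPYLORI_INV),
                tok(r.country, _COUNTRY_INV),
                tok(r.ethnicity, _ETHNICITY_INV),
                tok(r.sex),
                NA if r.age is None else r.age,
                tok(r.histology, _HISTOLOGY_INV),
                tok(r.anatomic_site),
                tok(r.stage),
            ])


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

MAF_COLUMNS = (
    "biopsy_id", "patient_id", "chrom", "pos", "ref", "alt",
    "gene", "effect", "trinucleotide_context", "alt_reads", "depth", "called",
)


def read_variant_table(path: str | Path, dialect: str = "maf_tsv",
                       patient_id: str | None = None) -> list[VariantCall]:
    """Read per-biopsy somatic variant calls.

    Parameters
    ----------
    dialect
        ``"maf_tsv"`` — one variant-biopsy row per line with the
        :data:`MAF_COLUMNS` header; or ``"vcf_minimal"`` — a VCF 4.2 file
        with per-sample ``AD``/``DP`` FORMAT fields, where sample names are
        biopsy ids and multi-allelic rows are split into one record per
        alternate allele.
    patient_id
        Required for the VCF dialect (a VCF carries no patient column).
    """
    if dialect == "maf_tsv":
        return _read_maf_tsv(path)
    if dialect == "vcf_minimal":
        if patient_id is None:
            raise ValueError("patient_id is required for the vcf_minimal dialect")
        return _read_vcf_minimal(path, patient_id)
    raise ValueError(f"unsupported dialect {dialect!r}")


def _read_maf_tsv(path: str | Path) -> list[VariantCall]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "biopsy_id", "alt_reads", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            pos = int(d["pos"])
            alt_reads = int(d["alt_reads"])
            depth = int(d["depth"])
        except ValueError as exc:
            raise ParseError(f"{path} row {i}: malformed number ({exc})") from None
        def opt(col: str) -> str | None:
            v = d.get(col, NA)
            return None if v in (NA, "") else v
        calls.append(
            VariantCall(
                biopsy_id=d["biopsy_id"],
                patient_id=d.get("patient_id", ""),
                chrom=d["chrom"],
                pos=pos,
                ref=d["ref"],
                alt=d["alt"],
                gene=opt("gene"),
                effect=opt("effect"),
                trinucleotide_context=opt("trinucleotide_context"),
                alt_reads=alt_reads,
                depth=depth,
                called=d.get("called", "True") in ("True", "true", "1"),
            )
        )
    return calls


def _read_vcf_minimal(path: str | Path, patient_id: str) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                for sample, sdata in rec.samples.items():
                    ad = sdata.get("AD")
                    dp = sdata.get("DP")
                    if ad is None or ad[0] is None:
                        continue
                    alt_reads = ad[ai + 1] if len(ad) > ai + 1 else 0
                    if alt_reads is None:
                        continue
                    depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                    calls.append(
                        VariantCall(
                            biopsy_id=sample,
                            patient_id=patient_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            alt_reads=int(alt_reads),
                            depth=depth,
                        )
                    )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as MAF-like TSV (the loss-free round-trip format)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MAF_COLUMNS)
        for c in calls:
            w.writerow([
                c.biopsy_id, c.patient_id, c.chrom, c.pos, c.ref, c.alt,
                NA if c.gene is None else c.gene,
                NA if c.effect is None else c.effect,
                NA if c.trinucleotide_context is None else c.trinucleotide_context,
                c.alt_reads, c.depth, c.called,
            ])


# ---------------------------------------------------------------------------
# panel, CNV segments, MSI histograms, EBV fractions
# ---------------------------------------------------------------------------

def read_panel(bed_path: str | Path, cds_path: str | Path | None = None) -> PanelDefinition:
    """Read a panel BED (half-open 0-based) plus optional gene/CDS-kbp TSV."""
    regions: list[tuple[str, int, int]] = []
    with Path(bed_path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{bed_path}: BED line with <3 fields: {line!r}")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    cds: dict[str, float] = {}
    if cds_path is not None:
        df = pd.read_csv(cds_path, sep="\t", dtype={0: str})
        gene_col, len_col = df.columns[:2]
        cds = dict(zip(df[gene_col], df[len_col].astype(float)))
    return PanelDefinition(target_regions=tuple(regions), gene_cds_kbp=cds)


def write_panel(panel: PanelDefinition, bed_path: str | Path,
                cds_path: str | Path | None = None) -> None:
    with Path(bed_path).open("w") as fh:
        for chrom, start, end in panel.target_regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    if cds_path is not None:
        with Path(cds_path).open("w") as fh:
            fh.write("gene\tcds_kbp\n")
            for g, l in panel.gene_cds_kbp.items():
                fh.write(f"{g}\t{l}\n")


def read_cnv_segments(path: str | Path) -> "list[CNVSegment]":
    from .subtyping import CNVSegment

    df = pd.read_csv(path, sep="\t")
    return [
        CNVSegment(
            biopsy_id=str(r.biopsy_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), log2_ratio=float(r.log2_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def write_cnv_segments(segments: "Iterable[CNVSegment]", path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("biopsy_id\tchrom\tstart\tend\tlog2_ratio\n")
        for s in segments:
            fh.write(f"{s.biopsy_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.log2_ratio}\n")


def read_msi_histograms(path: str | Path) -> "dict[str, list[MSILocus]]":
    """Read a long-format MSI histogram TSV.

    Columns: ``patient_id, locus_id, sample_role (tumor|normal),
    repeat_length, read_count``.  Returns per-patient locus lists.
    """
    from .subtyping import MSILocus

    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[MSILocus]] = {}
    for (pid, locus), grp in df.groupby(["patient_id", "locus_id"], sort=True):
        tumor: dict[int, int] = {}
        normal: dict[int, int] = {}
        for r in grp.itertuples(index=False):
            target = tumor if r.sample_role == "tumor" else normal
            target[int(r.repeat_length)] = target.get(int(r.repeat_length), 0) + int(r.read_count)
        out.setdefault(str(pid), []).append(
            MSILocus(locus_id=str(locus), tumor_hist=tumor, normal_hist=normal)
        )
    return out


def write_msi_histograms(loci_by_patient: "Mapping[str, Sequence[MSILocus]]",
                         path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("patient_id\tlocus_id\tsample_role\trepeat_length\tread_count\n")
        for pid in loci_by_patient:
            for locus in loci_by_patient[pid]:
                for role, hist in (("tumor", locus.tumor_hist), ("normal", locus.normal_hist)):
                    for length in sorted(hist):
                        fh.write(f"{pid}\t{locus.locus_id}\t{role}\t{length}\t{hist[length]}\n")


def read_ebv_fractions(path: str | Path) -> dict[str, dict[str, float]]:
    """Read per-biopsy EBV on-target read fractions: patient -> biopsy -> fraction."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.patient_id), {})[str(r.biopsy_id)] = float(r.ebv_read_fraction)
    return out


def write_ebv_fractions(fractions: Mapping[str, Mapping[str, float]],
                        path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("patient_id\tbiopsy_id\tebv_read_fraction\n")
        for pid in fractions:
            for bid, frac in fractions[pid].items():
                fh.write(f"{pid}\t{bid}\t{frac}\n")


# ---------------------------------------------------------------------------
# signature catalog
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path):
    """Read a 96-context signature catalog TSV (first column = context label)."""
    from .signatures import SignatureCatalog

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog.from_frame(df)


def write_signature_catalog(catalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: "ClonalTree", path: str | Path) -> None:
    """Serialize a clonal tree to a Newick file.

    Leaf names are biopsy ids; branch lengths are mutation counts; the trunk
    (full-biopsy-set) edge length is written as the root edge length.
    """
    with Path(path).open("w") as fh:
        fh.write(tree.to_newick() + "\n")


def newick_string(tree: "ClonalTree") -> str:
    buf = _io.StringIO()
    buf.write(tree.to_newick())
    return buf.getvalue()
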
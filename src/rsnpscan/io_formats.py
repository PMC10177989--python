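"""Readers and writers for every external table the pipeline touches.

Coordinate conventions
----------------------
All positions handled inside the package are **1-based**. SNP indexes
(VCF-subset or TSV) are already 1-based and kept as-is. BED input (gene
models, peak intervals) is 0-based half-open and converted on read; peak
intervals retain their native 0-based half-open ``start``/``end`` because
overlap arithmetic is done explicitly where they are used.

The pipeline starts from *allelic count tables*, not reads: upstream
trimming, alignment to the reference genome and to each individual's
alternative-reference sequence, and per-sample pooling of sequencing files
are abstracted into one count pair per (SNP, individual, assay, alignment
target).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed assay vocabulary: the transcriptome plus the four activating
#: histone modifications profiled in AD lateral temporal lobe.
ASSAYS: tuple[str, ...] = ("RNA", "H3K4me3", "H3K4me1", "H3K27ac", "H3K9ac")
HISTONE_MARKS: tuple[str, ...] = tuple(a for a in ASSAYS if a != "RNA")
ALIGNMENT_TARGETS: tuple[str, ...] = ("reference", "alternative")
BASES = frozenset("ACGT")

#: Function categories of epigenetic regulators: histone-modification
#: writers/readers/erasers and chromatin remodelers, each optionally acting
#: as a complex cofactor rather than the primary enzyme.
EPI_FUNCTION_BASES: tuple[str, ...] = ("HMW", "HMR", "HME", "CR")

COUNT_COLUMNS = [
    "snp_id", "individual", "assay", "alignment_target", "ref_reads", "alt_reads",
]
COUNT_KEY = ["snp_id", "individual", "assay", "alignment_target"]


class FormatError(ValueError):
    """A malformed or contract-violating input file."""


# ---------------------------------------------------------------------------
# domain record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One biallelic indexed SNP (positions 1-based)."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.snp_id or self.snp_id == ".":
            raise FormatError("SNP record requires a non-empty identifier")
        if self.pos < 1:
            raise FormatError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if allele not in BASES:
                raise FormatError(
                    f"{self.snp_id}: {name} allele {allele!r} not a single base in ACGT"
                )
        if self.ref == self.alt:
            raise FormatError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class AlleleCountRecord:
    """Reads supporting each allele at one SNP, for one individual, assay,
    and alignment target (reference genome vs individual alternative
    reference)."""

    snp_id: str
    individual: str
    assay: str
    alignment_target: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise FormatError(
                f"unknown assay {self.assay!r}; allowed: {', '.join(ASSAYS)}"
            )
        if self.alignment_target not in ALIGNMENT_TARGETS:
            raise FormatError(
                f"unknown alignment_target {self.alignment_target!r}; "
                f"allowed: {', '.join(ALIGNMENT_TARGETS)}"
            )
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise FormatError(f"{self.snp_id}: negative read count")


@dataclass(frozen=True)
class GeneModel:
    """One transcription start site of a gene (tss 1-based)."""

    symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.symbol}: strand must be '+' or '-'")
        if self.tss < 1:
            raise FormatError(f"{self.symbol}: tss must be >= 1")


@dataclass(frozen=True)
class PeakRecord:
    """A ChIP-seq peak call for a DNA/chromatin-binding protein.

    ``start``/``end`` follow BED: 0-based, half-open.
    """

    protein: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.protein:
            raise FormatError("peak record requires a protein symbol")
        if not self.start < self.end:
            raise FormatError(
                f"{self.protein}: peak start {self.start} must be < end {self.end}"
            )


@dataclass
class GeneSetTable:
    """A named annotation table keyed by gene symbol (or SNP id for a GWAS
    extract) with optional attribute columns."""

    name: str
    key_column: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.key_column not in self.table.columns:
            raise FormatError(
                f"gene set {self.name!r}: key column {self.key_column!r} missing"
            )
        self.table = self.table.drop_duplicates().reset_index(drop=True)
        dup = self.table[self.key_column].duplicated()
        if dup.any():
            keys = sorted(self.table.loc[dup, self.key_column].unique())
            raise FormatError(
                f"gene set {self.name!r}: conflicting duplicate keys {keys[:5]}"
            )

    @property
    def keys(self) -> set[str]:
        return set(self.table[self.key_column])


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Tabulate a collection of dataclass records."""
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_snp_index(path: str | Path, dialect: str = "vcf_subset") -> pd.DataFrame:
    """Read a SNP index into a frame of biallelic SNVs.

    Parameters
    ----------
    path
        A VCF-subset file (``CHROM POS ID REF ALT`` as the first five
        columns, ``##`` meta lines and a ``#CHROM`` header tolerated) or a
        TSV with header ``snp_id chrom pos ref alt``.
    dialect
        ``"vcf_subset"`` or ``"tsv"``.

    Multiallelic records and indels are dropped with a logged count; the
    analysis keeps only indexed biallelic SNVs. Duplicate SNP identifiers
    raise :class:`FormatError`.
    """
    path = Path(path)
    if dialect not in ("vcf_subset", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[dict] = []
    n_dropped = 0
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "vcf_subset":
                if line.startswith("##") or line.startswith("#CHROM"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: expected >=5 columns")
                chrom, pos_s, snp_id, ref, alt = fields[:5]
            else:
                fields = line.split("\t")
                if header_cols is None:
                    header_cols = fields
                    expected = ["snp_id", "chrom", "pos", "ref", "alt"]
                    if fields[: len(expected)] != expected:
                        raise FormatError(
                            f"{path}:{lineno}: TSV header must start with {expected}"
                        )
                    continue
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 columns")
                snp_id, chrom, pos_s, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: position {pos_s!r} not an integer") from exc
            ref, alt = ref.upper(), alt.upper()
            if "," in alt or len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= BASES:
                n_dropped += 1
                continue
            try:
                rec = SnpRecord(snp_id, chrom, pos, ref, alt)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append(vars(rec))
    if n_dropped:
        logger.info("%s: dropped %d multiallelic/indel records", path, n_dropped)
    if not rows:
        logger.warning("%s: no usable SNP records", path)
        frame = pd.DataFrame(columns=["snp_id", "chrom", "pos", "ref", "alt"])
    else:
        frame = pd.DataFrame(rows)
    dup = frame["snp_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate snp_id {sorted(frame.loc[dup, 'snp_id'].unique())[:5]}"
        )
    frame.attrs["n_dropped"] = n_dropped
    return frame


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-allele read-count TSV.

    The file must carry the header columns ``snp_id individual assay
    alignment_target ref_reads alt_reads``. The assay and alignment-target
    vocabularies are closed; counts must be non-negative integers; duplicate
    (snp, individual, assay, target) keys raise — pooling technical
    replicates is the explicit :func:`pool_counts` operation, never silent.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frame = frame[COUNT_COLUMNS].copy()
    for col in ("ref_reads", "alt_reads"):
        try:
            values = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric {col}") from exc
        if (values < 0).any() or (values % 1 != 0).any():
            raise FormatError(f"{path}: {col} must be non-negative integers")
        frame[col] = values.astype(int)
    bad_assay = sorted(set(frame["assay"]) - set(ASSAYS))
    if bad_assay:
        raise FormatError(
            f"{path}: unknown assay values {bad_assay}; allowed: {', '.join(ASSAYS)}"
        )
    bad_target = sorted(set(frame["alignment_target"]) - set(ALIGNMENT_TARGETS))
    if bad_target:
        raise FormatError(
            f"{path}: unknown alignment_target values {bad_target}; "
            f"allowed: {', '.join(ALIGNMENT_TARGETS)}"
        )
    if frame.duplicated(COUNT_KEY).any():
        dup_keys = frame.loc[frame.duplicated(COUNT_KEY), COUNT_KEY].head(3)
        raise FormatError(
            f"{path}: duplicate count keys (pool replicates explicitly with "
            f"pool_counts): {dup_keys.to_dict('records')}"
        )
    return frame.reset_index(drop=True)


def pool_counts(
    counts: pd.DataFrame,
    within: Sequence[str] = ("snp_id", "individual", "assay", "alignment_target"),
) -> pd.DataFrame:
    """Sum read counts over technical replicates within each count key.

    ``within`` names the key columns preserved by pooling and must contain
    all of ``snp_id``, ``assay`` and ``alignment_target`` plus, by default,
    ``individual``: pooling happens across sequencing files of one sample,
    never across assays or alignment targets (and not across individuals by
    default). Total ref and alt read counts are conserved.
    """
    within = list(within)
    required = {"snp_id", "assay", "alignment_target"}
    if not required <= set(within):
        forbidden = sorted(required - set(within))
        raise ValueError(
            f"pooling across {forbidden} is forbidden; 'within' must retain them"
        )
    if not set(within) <= set(COUNT_KEY):
        raise ValueError(f"'within' must be a subset of {COUNT_KEY}")
    pooled = (
        counts.groupby(within, as_index=False, sort=True)[["ref_reads", "alt_reads"]]
        .sum()
    )
    for col in COUNT_KEY:
        if col not in pooled.columns:
            pooled[col] = "pooled"
    return pooled[COUNT_COLUMNS]


def read_gene_models(path: str | Path, dialect: str = "bed6") -> pd.DataFrame:
    """Read transcript records into one row per distinct (symbol, TSS).

    ``bed6`` input is 0-based half-open: the TSS is ``start + 1`` on the +
    strand and ``end`` on the − strand (both 1-based). ``tsv`` input carries
    header ``symbol chrom strand tss`` with a 1-based TSS. Duplicate
    (symbol, chrom, strand, tss) records collapse to one.
    """
    path = Path(path)
    rows: list[dict] = []
    if dialect == "bed6":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, start_s, end_s, symbol, _score, strand = fields[:6]
                start, end = int(start_s), int(end_s)
                tss = start + 1 if strand == "+" else end
                try:
                    rec = GeneModel(symbol, chrom, strand, tss)
                except FormatError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                rows.append(vars(rec))
    elif dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
        for i, row in frame.iterrows():
            try:
                rec = GeneModel(str(row["symbol"]), str(row["chrom"]), str(row["strand"]), int(row["tss"]))
            except FormatError as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
            rows.append(vars(rec))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "tss"])
    return frame.drop_duplicates().reset_index(drop=True)


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED4 peak file (``chrom start end protein``), 0-based half-open."""
    path = Path(path)
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 needs 4 columns")
            chrom, start_s, end_s, protein = fields[:4]
            try:
                rec = PeakRecord(protein, chrom, int(start_s), int(end_s))
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append(vars(rec))
    return pd.DataFrame(rows, columns=["protein", "chrom", "start", "end"])


def read_gene_set(path: str | Path, name: str, key_column: str | None = None) -> GeneSetTable:
    """Read a gene-set annotation TSV into a :class:`GeneSetTable`.

    The key column defaults to ``snp_id`` for tables that carry one (GWAS
    extracts), else ``gene``.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if key_column is None:
        key_column = "snp_id" if "snp_id" in frame.columns else "gene"
    return GeneSetTable(name=name, key_column=key_column, table=frame)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write each table as ``<name>.tsv`` with a run-metadata comment header.

    Metadata lines are ``# key=value``; column order is the frame's order
    and is stable across runs, so identical inputs produce byte-identical
    reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta_lines = "".join(
        f"# {k}={v}\n" for k, v in (metadata or {}).items()
    )
    for name, table in tables.items():
        if not re.fullmatch(r"[\w.-]+", name):
            raise ValueError(f"unsafe report table name {name!r}")
        target = out_dir / f"{name}.tsv"
        with open(target, "w") as fh:
            fh.write(meta_lines)
            table.to_csv(fh, sep="\t", index=False)
        written.append(target)
    return written


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read one report TSV back, returning (table, metadata)."""
    path = Path(path)
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    metadata[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        table = pd.read_csv(fh, sep="\t")
    return table, metadata
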
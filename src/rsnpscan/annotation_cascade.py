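"""Annotation joins: DEG lists, epigenetic-regulator catalog, GWAS extract,
and the ENCODE-style regulator cascade.

The cascade logic: for every DNA/chromatin-binding protein with peak calls,
find the AD-related gene promoters its peaks overlap (>= 1 shared base).
The protein becomes a *regulator link* only if the promoter of its own gene
contains at least one discovered rSNP — i.e. the regulator's expression is
itself under putative allele-specific control, propagating the variant's
effect to every target it binds.

Epigenetic-regulator function categories follow the writer/reader/eraser/
remodeler scheme (HMW/HMR/HME/CR), each optionally as a complex cofactor; a
gene may belong to several categories, so category counts may sum to more
than the number of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import EPI_FUNCTION_BASES, FormatError, GeneSetTable
from .rsnp_discovery import PromoterIndex

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["regulator", "rsnp_ids", "target_genes", "n_targets"]


@dataclass(frozen=True)
class RegulatorLink:
    """A regulator gene with rSNP(s) in its own promoter, linked to the
    target genes whose promoters its protein's peaks overlap."""

    regulator: str
    rsnp_ids: tuple[str, ...]
    targets: tuple[str, ...]

    @property
    def n_targets(self) -> int:
        return len(set(self.targets))


def parse_epi_functions(text: str) -> list[tuple[str, bool]]:
    """Parse a function annotation like ``"HME, HMW cofactor"``.

    Returns ``(base_category, is_cofactor)`` pairs with base in
    HMW/HMR/HME/CR. The literal token ``TF`` (a transcription-factor role
    noted alongside epigenetic ones in some catalogs) is accepted and
    skipped; an empty annotation yields an empty list (unclassified entry).
    Any other label raises.
    """
    out: list[tuple[str, bool]] = []
    for token in str(text).split(","):
        token = token.strip()
        if not token or token == "#":
            continue
        if token == "TF":
            continue
        parts = token.split()
        base = parts[0]
        if base not in EPI_FUNCTION_BASES or len(parts) > 2 or (
            len(parts) == 2 and parts[1] != "cofactor"
        ):
            raise FormatError(
                f"unknown epigenetic function category {token!r}; "
                f"allowed bases: {', '.join(EPI_FUNCTION_BASES)} (+ 'cofactor')"
            )
        out.append((base, len(parts) == 2))
    return out


# ---------------------------------------------------------------------------
# gene-set joins
# ---------------------------------------------------------------------------

def join_degs(
    assignments: pd.DataFrame,
    deg_up: GeneSetTable,
    deg_down: GeneSetTable,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Inner-join promoter-assigned rSNPs with up/down DEG lists.

    Returns the joined table (snp_id, gene, direction) and per-direction
    distinct counts of rSNPs and genes. A gene present in both DEG lists
    violates the one-direction invariant and raises.
    """
    both = deg_up.keys & deg_down.keys
    if both:
        raise FormatError(f"genes in both DEG directions: {sorted(both)[:5]}")
    assigned = assignments.loc[assignments["gene"] != "", ["snp_id", "gene"]]
    pieces = []
    for direction, gene_set in (("up", deg_up), ("down", deg_down)):
        hit = assigned[assigned["gene"].isin(gene_set.keys)].copy()
        hit["direction"] = direction
        pieces.append(hit)
    joined = (
        pd.concat(pieces, ignore_index=True)
        .drop_duplicates()
        .sort_values(["direction", "gene", "snp_id"], kind="stable")
        .reset_index(drop=True)
    )
    summary = {
        direction: {
            "n_rsnps": int(sub["snp_id"].nunique()),
            "n_genes": int(sub["gene"].nunique()),
        }
        for direction, sub in (
            ("up", joined[joined["direction"] == "up"]),
            ("down", joined[joined["direction"] == "down"]),
        )
    }
    return joined, summary


def join_epifactors(
    assignments: pd.DataFrame,
    epi: GeneSetTable,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join promoter-assigned rSNPs with an epigenetic-regulator catalog.

    The catalog needs a ``function`` column in the HMW/HMR/HME/CR (+
    cofactor) vocabulary. Category counts use multi-membership: one gene
    with functions HMW and HME increments both, so the category sum may
    exceed the distinct-gene total.
    """
    if "function" not in epi.table.columns:
        raise FormatError(f"gene set {epi.name!r} lacks a 'function' column")
    functions = dict(zip(epi.table[epi.key_column], epi.table["function"]))
    for text in functions.values():
        parse_epi_functions(text)  # vocabulary validation up front
    assigned = assignments.loc[assignments["gene"] != "", ["snp_id", "gene"]]
    joined = assigned[assigned["gene"].isin(functions)].drop_duplicates().copy()
    joined["function"] = joined["gene"].map(functions)
    joined = joined.sort_values(["gene", "snp_id"], kind="stable").reset_index(drop=True)
    counts = {base: 0 for base in EPI_FUNCTION_BASES}
    for gene in joined["gene"].unique():
        for base, _cofactor in set(parse_epi_functions(functions[gene])):
            counts[base] += 1
    counts["n_rsnps"] = int(joined["snp_id"].nunique())
    counts["n_genes"] = int(joined["gene"].nunique())
    return joined, counts


def join_gwas(rsnps: pd.DataFrame, gwas: GeneSetTable) -> pd.DataFrame:
    """Intersect discovered rSNPs with a GWAS-catalog extract keyed by snp_id.

    Returns the (possibly empty) overlap with the catalog's metadata
    columns; duplicate catalog rows for one SNP are collapsed upstream by
    :class:`GeneSetTable`.
    """
    catalog = gwas.table.drop_duplicates(gwas.key_column)
    merged = rsnps[["snp_id"]].drop_duplicates().merge(
        catalog, left_on="snp_id", right_on=gwas.key_column, how="inner"
    )
    return merged.sort_values("snp_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# regulator cascade
# ---------------------------------------------------------------------------

def regulator_cascade(
    ad_promoters: pd.DataFrame,
    peaks: pd.DataFrame,
    assignments: pd.DataFrame,
    regulator_promoters: pd.DataFrame,
    alias: dict[str, str] | None = None,
) -> list[RegulatorLink]:
    """Build regulator links from peak overlaps and promoter rSNPs.

    Parameters
    ----------
    ad_promoters
        Promoter windows of the AD-related genes (targets).
    peaks
        Peak intervals per protein (BED-style 0-based half-open).
    assignments
        Promoter-assigned rSNPs (output of ``assign_to_promoters``).
    regulator_promoters
        Promoter windows covering the genes that encode the peak proteins
        (used only through ``assignments``; passed for symmetry of the
        contract and for resolving which proteins have a gene model).
    alias
        Optional protein-symbol -> gene-symbol map. Resolution is exact:
        proteins whose gene symbol has no promoter window are logged and
        skipped, never fuzzy-matched.
    """
    alias = alias or {}
    index = PromoterIndex(ad_promoters)
    regulator_genes = set(regulator_promoters["gene"])
    rsnps_by_gene = (
        assignments.loc[assignments["gene"] != ""]
        .groupby("gene")["snp_id"]
        .agg(lambda s: tuple(sorted(set(s))))
        .to_dict()
    )
    links: list[RegulatorLink] = []
    for protein, protein_peaks in peaks.groupby("protein", sort=True):
        gene = alias.get(protein, protein)
        if gene not in regulator_genes:
            logger.info("peak protein %s has no resolvable gene model; skipped", protein)
            continue
        targets: set[str] = set()
        for peak in protein_peaks.itertuples():
            # BED half-open [start, end) -> 1-based inclusive [start+1, end]
            hits = index.query_interval(peak.chrom, peak.start + 1, peak.end)
            targets.update(hits["gene"])
        if not targets:
            continue
        rsnp_ids = rsnps_by_gene.get(gene, ())
        if not rsnp_ids:
            continue  # regulator's own promoter carries no rSNP
        links.append(RegulatorLink(gene, tuple(rsnp_ids), tuple(sorted(targets))))
    return links


def links_to_frame(links: list[RegulatorLink]) -> pd.DataFrame:
    rows = [
        {
            "regulator": link.regulator,
            "rsnp_ids": ",".join(link.rsnp_ids),
            "target_genes": ",".join(sorted(set(link.targets))),
            "n_targets": link.n_targets,
        }
        for link in sorted(links, key=lambda l: l.regulator)
    ]
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def build_regulator_tables(
    links: list[RegulatorLink],
    epi: GeneSetTable | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split regulator links into a transcription-factor table and an
    epigenetic-regulator table.

    Regulators present in the epigenetic catalog land in the second table
    with their function/modification/complex annotation; all others land in
    the first. Both tables are emitted with headers even when empty.
    """
    frame = links_to_frame(links)
    epi_cols = ["function", "modification", "complex", "specific_target"]
    if epi is None or frame.empty:
        epi_genes: set[str] = set() if epi is None else epi.keys
    else:
        epi_genes = epi.keys
    is_epi = frame["regulator"].isin(epi_genes) if not frame.empty else pd.Series(dtype=bool)
    tf_table = frame.loc[~is_epi].reset_index(drop=True) if not frame.empty else frame.copy()
    epi_table = frame.loc[is_epi].reset_index(drop=True) if not frame.empty else frame.copy()
    for col in epi_cols:
        epi_table[col] = ""
    if epi is not None and not epi_table.empty:
        annot = epi.table.set_index(epi.key_column)
        for col in epi_cols:
            if col in annot.columns:
                epi_table[col] = epi_table["regulator"].map(annot[col]).fillna("")
    return tf_table, epi_table


# ---------------------------------------------------------------------------
# packaged worked-example tables
# ---------------------------------------------------------------------------

_EXAMPLE_FILES = {
    "upregulated_epi": "ad_epi_regulators_up.tsv",
    "tf_links": "ad_tf_links.tsv",
    "epi_links": "ad_epi_links.tsv",
}


def load_example_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged worked-example tables.

    Three small curated tables around Alzheimer's-disease brain regulation:
    upregulated AD-related genes that are epigenetic regulators with rSNPs
    in their promoters (``upregulated_epi``); transcription factors linked
    to AD-related target genes through promoter peak overlaps
    (``tf_links``); and the analogous links for epigenetic regulators
    (``epi_links``).
    """
    out: dict[str, pd.DataFrame] = {}
    package = resources.files("rsnpscan.data")
    for key, filename in _EXAMPLE_FILES.items():
        with (package / filename).open() as fh:
            out[key] = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    return out


def _example_links(frame: pd.DataFrame) -> list[RegulatorLink]:
    return [
        RegulatorLink(
            regulator=row["protein"],
            rsnp_ids=tuple(sorted(set(row["rsnp_ids"].split(",")))),
            targets=tuple(sorted(set(row["target_genes"].split(",")))),
        )
        for _, row in frame.iterrows()
    ]


def summarize_example_tables() -> dict[str, int]:
    """Recompute the headline counts of the packaged worked example.

    All values are derived from the shipped tables through the package's
    own link/ table machinery — nothing is hard-coded:

    - ``upregulated_epi_genes``: distinct upregulated epigenetic regulators
      with promoter rSNPs.
    - ``tf_regulators`` / ``epi_regulators``: distinct regulators in the
      two link tables, and ``shared_regulators`` / ``all_regulators`` their
      overlap and union.
    - ``cascade_target_genes``: distinct AD-related targets across both.
    - ``new_epi_regulators`` / ``new_epi_rsnps``: epigenetic-regulator
      links beyond the upregulated-DEG table, and their distinct rSNPs.
    - ``arid1b_targets``: target count of the ARID1B link.
    """
    tables = load_example_tables()
    epi_catalog = GeneSetTable(
        name="EpiFactors_example",
        key_column="protein",
        table=tables["epi_links"][
            ["protein", "function", "modification", "complex", "specific_target"]
        ].drop_duplicates("protein"),
    )
    links = {
        link.regulator: link
        for link in _example_links(tables["tf_links"]) + _example_links(tables["epi_links"])
    }
    tf_table, epi_table = build_regulator_tables(list(links.values()), epi_catalog)

    tf_named = set(tables["tf_links"]["protein"])
    epi_named = set(tables["epi_links"]["protein"])
    table1_genes = set(tables["upregulated_epi"]["gene"])
    new_epi = epi_table.loc[~epi_table["regulator"].isin(table1_genes)]
    new_rsnps = {
        snp for cell in new_epi["rsnp_ids"] for snp in cell.split(",") if snp
    }
    all_targets = {
        gene
        for table in (tf_table, epi_table)
        for cell in table["target_genes"]
        for gene in cell.split(",")
        if gene
    }
    arid1b = epi_table.set_index("regulator")["n_targets"].get("ARID1B", 0)
    return {
        "upregulated_epi_genes": len(table1_genes),
        "tf_regulators": len(tf_named),
        "epi_regulators": len(epi_named),
        "shared_regulators": len(tf_named & epi_named),
        "all_regulators": len(tf_named | epi_named),
        "cascade_target_genes": len(all_targets),
        "new_epi_regulators": int(len(new_epi)),
        "new_epi_rsnps": len(new_rsnps),
        "arid1b_targets": int(arid1b),
    }
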
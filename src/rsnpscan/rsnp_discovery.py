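"""From allele-specific events to regulatory SNPs and promoter assignment.

A regulatory SNP (rSNP) is a SNP supported by at least one allele-specific
expression event *and* at least one allele-specific binding event (any
histone mark, any individual by default). Discovered rSNPs are assigned to
gene promoter windows of +/- w bp around each transcription start site
(default w = 1000); one rSNP may fall in the promoters of several genes and
an rSNP outside every window is kept but flagged intergenic.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROMOTER_COLUMNS = ["gene", "chrom", "strand", "tss", "start", "end"]
ASSIGNMENT_COLUMNS = ["snp_id", "chrom", "pos", "gene", "tss", "strand", "distance"]
RSNP_COLUMNS = [
    "snp_id", "n_ase_events", "n_asb_events", "marks", "individuals",
]


def build_promoters(gene_models: pd.DataFrame, w: int = 1000) -> pd.DataFrame:
    """Build one +/- w bp promoter window per distinct (gene, TSS).

    Windows are 1-based inclusive ``[tss - w, tss + w]`` with the start
    floored at 1; multiple TSSs of one gene keep separate windows. Strand
    determines only which end is the TSS and the sign of distances later;
    containment is strand-agnostic.
    """
    if w <= 0:
        raise ValueError("promoter half-width w must be > 0")
    promoters = gene_models.drop_duplicates(["symbol", "chrom", "strand", "tss"]).copy()
    promoters = promoters.rename(columns={"symbol": "gene"})
    promoters["start"] = (promoters["tss"] - w).clip(lower=1)
    promoters["end"] = promoters["tss"] + w
    return promoters[PROMOTER_COLUMNS].sort_values(
        ["chrom", "start", "gene"], kind="stable"
    ).reset_index(drop=True)


class PromoterIndex:
    """Per-chromosome interval index over promoter windows (1-based inclusive)."""

    def __init__(self, promoters: pd.DataFrame) -> None:
        self.promoters = promoters.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, group in self.promoters.groupby("chrom"):
            # IntervalTree is half-open; +1 makes [start, end] inclusive.
            self._trees[chrom] = IntervalTree.from_tuples(
                (row.start, row.end + 1, idx)
                for idx, row in zip(group.index, group.itertuples())
            )

    def query_point(self, chrom: str, pos: int) -> pd.DataFrame:
        """Promoter windows containing a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return self.promoters.iloc[0:0]
        hits = sorted(iv.data for iv in tree[pos])
        return self.promoters.loc[hits]

    def query_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Promoter windows sharing >= 1 base with a 1-based inclusive interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return self.promoters.iloc[0:0]
        hits = sorted(iv.data for iv in tree[start : end + 1])
        return self.promoters.loc[hits]


def call_rsnps(events: pd.DataFrame, same_individual: bool = False) -> pd.DataFrame:
    """Identify rSNPs: SNPs with >= 1 ASE and >= 1 ASB event.

    With ``same_individual=True`` both event classes must be observed in at
    least one common individual (a stricter reading; off by default). SNPs
    without a usable identifier (empty or '.') are excluded.
    """
    if events.empty:
        return pd.DataFrame(columns=RSNP_COLUMNS)
    events = events.loc[
        events["snp_id"].notna() & (events["snp_id"] != "") & (events["snp_id"] != ".")
    ]
    rows = []
    for snp_id, group in events.groupby("snp_id", sort=True):
        ase = group[group["event_class"] == "ASE"]
        asb = group[group["event_class"] == "ASB"]
        if ase.empty or asb.empty:
            continue
        if same_individual and not (set(ase["individual"]) & set(asb["individual"])):
            continue
        rows.append({
            "snp_id": snp_id,
            "n_ase_events": len(ase),
            "n_asb_events": len(asb),
            "marks": ",".join(sorted(set(asb["mark"]))),
            "individuals": ",".join(sorted(set(group["individual"]))),
        })
    return pd.DataFrame(rows, columns=RSNP_COLUMNS)


def assign_to_promoters(
    rsnps: pd.DataFrame,
    snp_index: pd.DataFrame,
    promoters: pd.DataFrame | PromoterIndex,
) -> pd.DataFrame:
    """Assign each rSNP to every promoter window containing it.

    Containment is inclusive on 1-based coordinates. The signed distance to
    the TSS is negative upstream of the TSS *on the gene's strand* (so on
    the − strand a position greater than the TSS is upstream). rSNPs with no
    promoter hit get one row with an empty gene and distance <NA>.
    """
    index = promoters if isinstance(promoters, PromoterIndex) else PromoterIndex(promoters)
    positions = snp_index.set_index("snp_id")[["chrom", "pos"]]
    missing = set(rsnps["snp_id"]) - set(positions.index)
    if missing:
        raise KeyError(f"rSNPs absent from the SNP index: {sorted(missing)[:5]}")
    rows = []
    for snp_id in rsnps["snp_id"]:
        chrom = positions.at[snp_id, "chrom"]
        pos = int(positions.at[snp_id, "pos"])
        hits = index.query_point(chrom, pos)
        if hits.empty:
            rows.append({
                "snp_id": snp_id, "chrom": chrom, "pos": pos,
                "gene": "", "tss": pd.NA, "strand": "", "distance": pd.NA,
            })
            continue
        for hit in hits.itertuples():
            distance = pos - hit.tss if hit.strand == "+" else hit.tss - pos
            rows.append({
                "snp_id": snp_id, "chrom": chrom, "pos": pos,
                "gene": hit.gene, "tss": hit.tss, "strand": hit.strand,
                "distance": distance,
            })
    frame = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return frame.sort_values(["snp_id", "gene", "tss"], kind="stable").reset_index(drop=True)


def summarize_discovery(assignments: pd.DataFrame) -> dict[str, int]:
    """Distinct-count summary: rSNPs, promoter-assigned rSNPs, genes hit.

    A gene is counted once however many rSNPs land in its promoter(s).
    """
    assigned = assignments.loc[assignments["gene"] != ""]
    return {
        "n_rsnps": int(assignments["snp_id"].nunique()),
        "n_promoter_rsnps": int(assigned["snp_id"].nunique()),
        "n_genes": int(assigned["gene"].nunique()),
    }
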
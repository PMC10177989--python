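"""Gene-set joins, the regulator cascade, and the worked-example tables."""

import pandas as pd
import pytest

from rsnpscan import annotation_cascade as cascade
from rsnpscan import rsnp_discovery as disc
from rsnpscan.io_formats import FormatError, GeneSetTable


def assignments_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "gene"]).assign(
        chrom="chr1", pos=0, tss=0, strand="+", distance=0
    )[["snp_id", "chrom", "pos", "gene", "tss", "strand", "distance"]]


def gene_set(name, genes, **extra):
    table = pd.DataFrame({"gene": genes, **extra})
    return GeneSetTable(name, "gene", table)


# join_degs -----------------------------------------------------------------

def test_deg_join_counts_distinct_rsnps_and_genes():
    assignments = assignments_frame([("rs1", "UPG"), ("rs2", "UPG"), ("rs3", "OTHER")])
    joined, summary = cascade.join_degs(
        assignments, gene_set("DEG_up", ["UPG"]), gene_set("DEG_down", ["DOWNG"])
    )
    assert summary["up"] == {"n_rsnps": 2, "n_genes": 1}
    assert summary["down"] == {"n_rsnps": 0, "n_genes": 0}
    assert set(joined["snp_id"]) == {"rs1", "rs2"}


def test_gene_in_both_deg_directions_rejected():
    with pytest.raises(FormatError, match="both"):
        cascade.join_degs(
            assignments_frame([]),
            gene_set("DEG_up", ["A"]), gene_set("DEG_down", ["A"]),
        )


def test_empty_deg_tables_give_empty_join():
    joined, summary = cascade.join_degs(
        assignments_frame([("rs1", "G")]),
        gene_set("DEG_up", []), gene_set("DEG_down", []),
    )
    assert joined.empty
    assert summary["up"]["n_rsnps"] == 0


# join_epifactors -----------------------------------------------------------

def test_multi_membership_category_counts():
    epi = gene_set("epi", ["G1"], function=["HMW, HME"])
    joined, counts = cascade.join_epifactors(
        assignments_frame([("rs1", "G1")]), epi
    )
    assert counts["HMW"] == 1 and counts["HME"] == 1
    assert counts["n_genes"] == 1 and counts["n_rsnps"] == 1


def test_category_sum_can_exceed_gene_total():
    epi = gene_set("epi", ["G1", "G2"], function=["HMW, CR", "HMW cofactor"])
    _, counts = cascade.join_epifactors(
        assignments_frame([("rs1", "G1"), ("rs2", "G2")]), epi
    )
    assert counts["HMW"] + counts["CR"] == 3 > counts["n_genes"] == 2


def test_unknown_category_label_rejected():
    epi = gene_set("epi", ["G1"], function=["XYZ"])
    with pytest.raises(FormatError, match="unknown epigenetic function"):
        cascade.join_epifactors(assignments_frame([("rs1", "G1")]), epi)


def test_empty_intersection_gives_zero_counts():
    epi = gene_set("epi", ["G9"], function=["CR"])
    joined, counts = cascade.join_epifactors(assignments_frame([("rs1", "G1")]), epi)
    assert joined.empty
    assert counts["n_genes"] == 0 and all(counts[b] == 0 for b in ("HMW", "HMR", "HME", "CR"))


def test_function_parser_accepts_cofactor_and_tf_tokens():
    assert cascade.parse_epi_functions("HME, HMW cofactor") == [("HME", False), ("HMW", True)]
    assert cascade.parse_epi_functions("HMW cofactor, TF") == [("HMW", True)]
    assert cascade.parse_epi_functions("") == []


# join_gwas -----------------------------------------------------------------

def test_gwas_disjoint_sets_empty_overlap():
    rsnps = pd.DataFrame({"snp_id": ["rs1", "rs2"]})
    gwas = GeneSetTable("GWAS_AD", "snp_id",
                        pd.DataFrame({"snp_id": ["rs9"], "trait": ["AD"]}))
    assert cascade.join_gwas(rsnps, gwas).empty


def test_gwas_shared_id_found_once():
    rsnps = pd.DataFrame({"snp_id": ["rs1"]})
    gwas = GeneSetTable("GWAS_AD", "snp_id",
                        pd.DataFrame({"snp_id": ["rs1", "rs1"],
                                      "trait": ["AD", "AD"]}))
    overlap = cascade.join_gwas(rsnps, gwas)
    assert len(overlap) == 1 and overlap.iloc[0]["trait"] == "AD"


# regulator_cascade ---------------------------------------------------------

def _cascade_setup():
    genes = pd.DataFrame({
        "symbol": ["REG", "NOSNP", "T1", "T2"],
        "chrom": "chr1", "strand": "+",
        "tss": [10_000, 20_000, 30_000, 40_000],
    })
    promoters = disc.build_promoters(genes, w=1000)
    ad_promoters = promoters[promoters["gene"].isin(["T1", "T2"])]
    return promoters, ad_promoters


def test_link_requires_rsnp_in_regulator_promoter():
    promoters, ad_promoters = _cascade_setup()
    peaks = pd.DataFrame({
        "protein": ["REG", "REG", "NOSNP"], "chrom": "chr1",
        "start": [29_800, 39_800, 29_800], "end": [30_200, 40_200, 30_200],
    })
    assignments = assignments_frame([("rs1", "REG")])
    links = cascade.regulator_cascade(ad_promoters, peaks, assignments, promoters)
    assert len(links) == 1
    link = links[0]
    assert link.regulator == "REG"
    assert link.targets == ("T1", "T2") and link.n_targets == 2
    assert link.rsnp_ids == ("rs1",)


def test_single_base_overlap_counts_and_outside_peak_does_not():
    promoters, ad_promoters = _cascade_setup()
    assignments = assignments_frame([("rs1", "REG")])
    # T1 window is [29000, 31000]; BED [28999, 29000) covers base 29000 only
    touching = pd.DataFrame({"protein": ["REG"], "chrom": "chr1",
                             "start": [28_999], "end": [29_000]})
    outside = pd.DataFrame({"protein": ["REG"], "chrom": "chr1",
                            "start": [28_900], "end": [28_999]})
    assert cascade.regulator_cascade(ad_promoters, touching, assignments, promoters)
    assert not cascade.regulator_cascade(ad_promoters, outside, assignments, promoters)


def test_unresolvable_protein_skipped():
    promoters, ad_promoters = _cascade_setup()
    peaks = pd.DataFrame({"protein": ["GHOST"], "chrom": "chr1",
                          "start": [29_800], "end": [30_200]})
    assignments = assignments_frame([("rs1", "REG")])
    assert cascade.regulator_cascade(ad_promoters, peaks, assignments, promoters) == []


def test_alias_table_resolves_protein_to_gene():
    promoters, ad_promoters = _cascade_setup()
    peaks = pd.DataFrame({"protein": ["REG-PROT"], "chrom": "chr1",
                          "start": [29_800], "end": [30_200]})
    assignments = assignments_frame([("rs1", "REG")])
    links = cascade.regulator_cascade(
        ad_promoters, peaks, assignments, promoters, alias={"REG-PROT": "REG"}
    )
    assert links and links[0].regulator == "REG"


def test_build_regulator_tables_splits_on_epi_catalog():
    links = [
        cascade.RegulatorLink("EPIREG", ("rs1",), ("T1",)),
        cascade.RegulatorLink("TFREG", ("rs2",), ("T1", "T2")),
    ]
    epi = gene_set("epi", ["EPIREG"], function=["CR"])
    tf_table, epi_table = cascade.build_regulator_tables(links, epi)
    assert list(tf_table["regulator"]) == ["TFREG"]
    assert list(epi_table["regulator"]) == ["EPIREG"]
    assert epi_table.iloc[0]["function"] == "CR"


def test_empty_links_give_two_empty_tables_with_headers():
    tf_table, epi_table = cascade.build_regulator_tables([], None)
    assert tf_table.empty and epi_table.empty
    assert "regulator" in tf_table.columns and "function" in epi_table.columns


def test_cascade_is_order_independent():
    promoters, ad_promoters = _cascade_setup()
    peaks = pd.DataFrame({
        "protein": ["REG", "REG"], "chrom": "chr1",
        "start": [39_800, 29_800], "end": [40_200, 30_200],
    })
    assignments = assignments_frame([("rs1", "REG")])
    fwd = cascade.regulator_cascade(ad_promoters, peaks, assignments, promoters)
    rev = cascade.regulator_cascade(
        ad_promoters, peaks.iloc[::-1].reset_index(drop=True), assignments, promoters
    )
    assert fwd == rev


# worked-example tables -----------------------------------------------------

def test_example_tables_load_with_expected_shape():
    tables = cascade.load_example_tables()
    assert len(tables["upregulated_epi"]) == 7
    assert len(tables["tf_links"]) == 13
    assert len(tables["epi_links"]) == 12


def test_example_summary_counts():
    summary = cascade.summarize_example_tables()
    assert summary == {
        "upregulated_epi_genes": 7,
        "tf_regulators": 13,
        "epi_regulators": 12,
        "shared_regulators": 3,
        "all_regulators": 22,
        "cascade_target_genes": 10,
        "new_epi_regulators": 11,
        "new_epi_rsnps": 15,
        "arid1b_targets": 6,
    }
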
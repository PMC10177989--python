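"""Synthetic pipeline inputs with known ground truth.

The generator emulates the data-generating process the caller pipeline
assumes: biallelic indexed SNPs on a toy genome, genes with transcription
start sites, Hardy–Weinberg genotypes from a minor-allele-frequency
distribution, and per-allele read counts at heterozygous sites for one
RNA-seq assay and four histone-mark ChIP-seq assays, each aligned to both a
reference genome and an individual alternative-reference sequence.

Allelic counts at a het site with total coverage ``n`` (negative-binomial
per assay) follow ``Binomial(n, p)`` where the reference-allele success
probability depends on the true allelic ratio ``rho`` and a multiplicative
mapping-bias odds factor ``b >= 1`` that works *pro-reference* on the
reference alignment target and *pro-alternative* on the alternative target:

    p_reference   = rho * b / (rho * b + (1 - rho))
    p_alternative = rho / (rho + (1 - rho) * b)

With ``rho = 0.5`` and ``b > 1`` the two targets are biased in opposite
directions while their odds multiply to the unbiased ``(rho/(1-rho))**2`` —
exactly the artifact a single-reference test mistakes for imbalance and the
dual concordant test cancels. An optional beta-binomial overdispersion
``phi`` perturbs ``p`` per site-individual draw; ``phi = 0`` keeps the pure
binomial model.

Ground truth (true ratios, imbalanced pairs, genotypes, promoter membership,
planted regulator links) is recorded for every emitted record, and a fixed
seed makes all outputs bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_cascade import RegulatorLink, links_to_frame
from .io_formats import ASSAYS, EPI_FUNCTION_BASES, HISTONE_MARKS, GeneSetTable

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale demo.

    Coverage is negative binomial per assay (mean ``coverage_mean``, shape
    ``coverage_size``); allelic imbalance is planted at ratio
    ``true_allelic_ratio`` in a ``fraction_imbalanced`` subset of SNPs
    (always RNA plus at least one histone mark, so planted SNPs are
    recoverable as rSNPs). ``mapping_bias`` is the odds factor b described
    in the module docstring; ``overdispersion`` is the beta-binomial phi.
    """

    n_individuals: int = 6
    n_snps: int = 2000
    n_genes: int = 60
    chrom: str = "chr1"
    gene_spacing: int = 20_000
    genome_offset: int = 50_000
    maf_low: float = 0.1
    maf_high: float = 0.5
    coverage_mean: float = 30.0
    coverage_size: float = 20.0
    true_allelic_ratio: float = 0.8
    mapping_bias: float = 1.0
    overdispersion: float = 0.0
    fraction_imbalanced: float = 0.05
    promoter_snp_fraction: float = 0.5
    n_deg_up: int = 12
    n_deg_down: int = 12
    n_epi: int = 10
    n_gwas_snps: int = 5
    n_regulators: int = 3
    targets_per_regulator: int = 3
    w: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.true_allelic_ratio <= 1:
            raise ValueError("true_allelic_ratio must be in (0, 1]")
        if self.mapping_bias < 1:
            raise ValueError("mapping_bias must be >= 1 (pro-reference odds factor)")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0 <= self.fraction_imbalanced < 1:
            raise ValueError("fraction_imbalanced must be in [0, 1)")
        if not 0 <= self.promoter_snp_fraction <= 1:
            raise ValueError("promoter_snp_fraction must be in [0, 1]")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValueError("DEG lists exceed the number of genes")


@dataclass
class SimulationTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    rho_map: pd.DataFrame           # snp_id, assay, rho (imbalanced pairs only)
    imbalanced_pairs: set[tuple[str, str]]
    planted_rsnps: set[str]
    genotypes: pd.DataFrame         # individual, snp_id, genotype in {0,1,2}
    promoter_map: pd.DataFrame      # snp_id, gene
    planted_links: list[RegulatorLink]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    snps: pd.DataFrame
    genes: pd.DataFrame
    peaks: pd.DataFrame
    gene_sets: dict[str, GeneSetTable]
    counts: pd.DataFrame
    truth: SimulationTruth


def target_success_probs(rho, b):
    """Reference-allele success probability on each alignment target.

    Returns ``(p_reference_target, p_alternative_target)`` for true allelic
    ratio ``rho`` and mapping-bias odds factor ``b``.
    """
    rho = np.asarray(rho, dtype=float)
    p_ref = rho * b / (rho * b + (1.0 - rho))
    p_alt = rho / (rho + (1.0 - rho) * b)
    return p_ref, p_alt


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Lay out genes, SNPs, peaks and annotation sets with planted truth.

    Returns ``(snps, genes, peaks, gene_sets, partial_truth)`` where the
    partial truth holds promoter membership, the planted regulator links,
    the planted rSNP ids and the per-(snp, assay) true allelic ratios.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    c = config
    w = c.w

    symbols = [f"G{i:04d}" for i in range(c.n_genes)]
    tss = c.genome_offset + np.arange(c.n_genes) * c.gene_spacing
    strands = rng.choice(["+", "-"], size=c.n_genes)
    genes = pd.DataFrame({
        "symbol": symbols, "chrom": c.chrom, "strand": strands, "tss": tss,
    })

    n_promoter = int(round(c.n_snps * c.promoter_snp_fraction))
    n_intergenic = c.n_snps - n_promoter
    promoter_capacity = c.n_genes * (2 * w + 1)
    gap_len = c.gene_spacing - 2 * w - 2000
    if n_promoter > promoter_capacity // 2 or gap_len <= 0 or \
            n_intergenic > (c.n_genes * gap_len) // 2:
        raise ValueError(
            "infeasible SNP placement: too many SNPs for the configured genome"
        )

    positions: list[int] = []
    snp_gene: list[str] = []
    used: set[int] = set()
    gene_order = rng.permutation(c.n_genes)
    for j in range(n_promoter):
        g = int(gene_order[j % c.n_genes])
        while True:
            pos = int(tss[g] + rng.integers(-w, w + 1))
            if pos not in used:
                break
        used.add(pos)
        positions.append(pos)
        snp_gene.append(symbols[g])
    for j in range(n_intergenic):
        g = int(rng.integers(0, c.n_genes))
        lo = tss[g] + w + 1000
        hi = tss[g] + c.gene_spacing - w - 1000
        while True:
            pos = int(rng.integers(lo, hi))
            if pos not in used:
                break
        used.add(pos)
        positions.append(pos)
        snp_gene.append("")

    order = np.argsort(positions, kind="stable")
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=c.n_snps)
    alt_shift = rng.integers(1, 4, size=c.n_snps)
    snps = pd.DataFrame({
        "snp_id": [f"rs{1_000_001 + i}" for i in range(c.n_snps)],
        "chrom": c.chrom,
        "pos": np.asarray(positions)[order],
        "ref": bases[ref_idx],
        "alt": bases[(ref_idx + alt_shift) % 4],
    })
    promoter_map = pd.DataFrame({
        "snp_id": snps["snp_id"],
        "gene": np.asarray(snp_gene, dtype=object)[order],
    })
    promoter_map = promoter_map[promoter_map["gene"] != ""].reset_index(drop=True)

    # gene sets: disjoint DEG directions; epi catalog may overlap DEGs
    shuffled = list(rng.permutation(symbols))
    deg_up = sorted(shuffled[: c.n_deg_up])
    deg_down = sorted(shuffled[c.n_deg_up : c.n_deg_up + c.n_deg_down])
    epi_genes = sorted(rng.choice(symbols, size=c.n_epi, replace=False))
    functions = []
    for _gene in epi_genes:
        k = int(rng.integers(1, 3))
        picks = rng.choice(len(EPI_FUNCTION_BASES), size=k, replace=False)
        tokens = []
        for p in picks:
            base = EPI_FUNCTION_BASES[int(p)]
            tokens.append(base + (" cofactor" if rng.random() < 0.3 else ""))
        functions.append(", ".join(tokens))

    # planted regulator cascade: regulators get >= 1 promoter SNP (the
    # planted rSNP) and peaks spanning each chosen target gene's TSS.
    deg_all = deg_up + deg_down
    candidates = [g for g in symbols if g not in deg_all]
    rng.shuffle(candidates)
    regulators = candidates[: c.n_regulators]
    decoy = candidates[c.n_regulators] if len(candidates) > c.n_regulators else None
    tss_by_gene = dict(zip(symbols, (int(t) for t in tss)))
    strand_by_gene = dict(zip(symbols, strands))

    planted_rsnps: set[str] = set()
    planted_links: list[RegulatorLink] = []
    peak_rows: list[dict] = []
    extra_snp_rows: list[dict] = []
    for i, reg in enumerate(regulators):
        reg_snps = promoter_map.loc[promoter_map["gene"] == reg, "snp_id"]
        if reg_snps.empty:
            snp_id = f"rs{2_000_001 + i}"
            pos = tss_by_gene[reg] + int(rng.integers(-w, w + 1))
            while pos in used:
                pos += 1
            used.add(pos)
            ref = str(rng.choice(bases))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            extra_snp_rows.append({
                "snp_id": snp_id, "chrom": c.chrom, "pos": pos, "ref": ref, "alt": alt,
            })
            promoter_map = pd.concat(
                [promoter_map, pd.DataFrame([{"snp_id": snp_id, "gene": reg}])],
                ignore_index=True,
            )
            chosen = snp_id
        else:
            chosen = str(reg_snps.iloc[0])
        planted_rsnps.add(chosen)
        targets = sorted(
            str(t) for t in rng.choice(deg_all, size=c.targets_per_regulator, replace=False)
        )
        for t in targets:
            center = tss_by_gene[t]
            peak_rows.append({
                "protein": reg, "chrom": c.chrom,
                "start": center - 300, "end": center + 300,  # 0-based half-open
            })
        # decoy peak outside any promoter window
        peak_rows.append({
            "protein": reg, "chrom": c.chrom,
            "start": tss_by_gene[reg] + 5 * w, "end": tss_by_gene[reg] + 5 * w + 400,
        })
        planted_links.append(
            RegulatorLink(reg, (chosen,), tuple(targets))
        )
    if decoy is not None and deg_all:
        # protein with peaks in a target promoter but no promoter rSNP:
        # must never produce a link
        t = deg_all[0]
        peak_rows.append({
            "protein": decoy, "chrom": c.chrom,
            "start": tss_by_gene[t] - 200, "end": tss_by_gene[t] + 200,
        })

    if extra_snp_rows:
        snps = pd.concat([snps, pd.DataFrame(extra_snp_rows)], ignore_index=True)
        snps = snps.sort_values("pos", kind="stable").reset_index(drop=True)

    # planted imbalance: fraction of SNPs, always RNA + >= 1 histone mark.
    # Regulator-promoter SNPs beyond the planted rSNP stay null so each
    # planted link's rSNP set is exactly its one planted variant.
    n_imb = int(round(len(snps) * c.fraction_imbalanced))
    regulator_promoter_snps = set(
        promoter_map.loc[promoter_map["gene"].isin(regulators), "snp_id"]
    )
    pool = [s for s in snps["snp_id"] if s not in regulator_promoter_snps]
    chosen_imb = [
        str(s)
        for s in rng.choice(pool, size=max(0, n_imb - len(planted_rsnps)), replace=False)
    ]
    rho_rows: list[dict] = []
    for snp_id in sorted(planted_rsnps) + sorted(chosen_imb):
        marks = rng.choice(HISTONE_MARKS, size=int(rng.integers(1, 3)), replace=False)
        for assay in ("RNA", *[str(m) for m in marks]):
            rho_rows.append({
                "snp_id": snp_id, "assay": assay, "rho": c.true_allelic_ratio,
            })
    rho_map = pd.DataFrame(rho_rows, columns=["snp_id", "assay", "rho"])

    gwas_pool = [s for s in snps["snp_id"] if s not in set(rho_map["snp_id"])]
    gwas_snps = sorted(rng.choice(gwas_pool, size=min(c.n_gwas_snps, len(gwas_pool)), replace=False))

    gene_sets = {
        "DEG_up": GeneSetTable("DEG_up", "gene", pd.DataFrame({"gene": deg_up})),
        "DEG_down": GeneSetTable("DEG_down", "gene", pd.DataFrame({"gene": deg_down})),
        "EpiFactors": GeneSetTable(
            "EpiFactors", "gene",
            pd.DataFrame({"gene": epi_genes, "function": functions}),
        ),
        "GWAS_AD": GeneSetTable(
            "GWAS_AD", "snp_id",
            pd.DataFrame({"snp_id": gwas_snps, "trait": "AD"}),
        ),
    }
    peaks = pd.DataFrame(peak_rows, columns=["protein", "chrom", "start", "end"])
    truth = SimulationTruth(
        rho_map=rho_map,
        imbalanced_pairs={(r["snp_id"], r["assay"]) for r in rho_rows},
        # every imbalanced SNP carries RNA + >= 1 mark imbalance, so the
        # ground-truth rSNP set is all imbalanced SNPs
        planted_rsnps=set(rho_map["snp_id"]),
        genotypes=pd.DataFrame(),
        promoter_map=promoter_map,
        planted_links=planted_links,
    )
    return snps, genes, peaks, gene_sets, truth


# ---------------------------------------------------------------------------
# genotypes and counts
# ---------------------------------------------------------------------------

def simulate_genotypes(
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    force_het: set[str] | None = None,
) -> pd.DataFrame:
    """Hardy–Weinberg genotypes (alt-allele dosage 0/1/2) per individual.

    MAF per SNP is uniform on [maf_low, maf_high]. SNPs in ``force_het``
    (planted rSNPs) are made heterozygous in at least half the individuals
    so the planted truth is testable at all.
    """
    force_het = force_het or set()
    individuals = [f"S{i + 1:02d}" for i in range(config.n_individuals)]
    maf = rng.uniform(config.maf_low, config.maf_high, size=len(snps))
    dosage = rng.binomial(2, maf[None, :].repeat(config.n_individuals, axis=0))
    frame = pd.DataFrame(
        dosage, index=individuals, columns=snps["snp_id"]
    ).stack().rename("genotype").reset_index()
    frame.columns = ["individual", "snp_id", "genotype"]
    if force_het:
        n_force = max(1, config.n_individuals // 2)
        forced_ind = set(individuals[:n_force])
        mask = frame["snp_id"].isin(force_het) & frame["individual"].isin(forced_ind)
        frame.loc[mask, "genotype"] = 1
    return frame


def simulate_allelic_counts(
    snps: pd.DataFrame,
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rho_map: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-allele read counts at every heterozygous (individual, SNP).

    One record per assay and alignment target; sites not listed in
    ``rho_map`` are null (rho = 0.5). See the module docstring for the
    count model.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    hets = genotypes.loc[genotypes["genotype"] == 1, ["individual", "snp_id"]]
    if hets.empty:
        return pd.DataFrame(
            columns=["snp_id", "individual", "assay", "alignment_target",
                     "ref_reads", "alt_reads"]
        )
    rho_lookup: dict[tuple[str, str], float] = {}
    if rho_map is not None and not rho_map.empty:
        rho_lookup = {
            (r.snp_id, r.assay): float(r.rho) for r in rho_map.itertuples()
        }
    pieces = []
    size = config.coverage_size
    p_nb = size / (size + config.coverage_mean)
    for assay in ASSAYS:
        block = hets.copy()
        block["assay"] = assay
        rho = np.array([
            rho_lookup.get((s, assay), 0.5) for s in block["snp_id"]
        ])
        p_ref_t, p_alt_t = target_success_probs(rho, config.mapping_bias)
        for target, p in (("reference", p_ref_t), ("alternative", p_alt_t)):
            n = rng.negative_binomial(size, p_nb, size=len(block))
            p_draw = p
            if config.overdispersion > 0:
                conc = 1.0 / config.overdispersion
                p_draw = rng.beta(np.clip(p * conc, 1e-9, None),
                                  np.clip((1.0 - p) * conc, 1e-9, None))
                p_draw = np.where(p >= 1.0, 1.0, np.where(p <= 0.0, 0.0, p_draw))
            ref = rng.binomial(n, p_draw)
            out = block.copy()
            out["alignment_target"] = target
            out["ref_reads"] = ref
            out["alt_reads"] = n - ref
            pieces.append(out)
    counts = pd.concat(pieces, ignore_index=True)
    counts = counts[[
        "snp_id", "individual", "assay", "alignment_target", "ref_reads", "alt_reads",
    ]]
    return counts.sort_values(
        ["snp_id", "individual", "assay", "alignment_target"], kind="stable"
    ).reset_index(drop=True)


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run the full generator: genome, genotypes, counts, truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    snps, genes, peaks, gene_sets, truth = simulate_genome(config, rng)
    genotypes = simulate_genotypes(snps, config, rng, force_het=truth.planted_rsnps)
    counts = simulate_allelic_counts(snps, genotypes, config, truth.rho_map, rng)
    truth.genotypes = genotypes
    return SimulatedStudy(config, snps, genes, peaks, gene_sets, counts, truth)


# ---------------------------------------------------------------------------
# site-level panels for calibration studies
# ---------------------------------------------------------------------------

def simulate_count_panel(
    pair_table: pd.DataFrame,
    n_individuals: int = 4,
    coverage_mean: float = 30.0,
    coverage_size: float = 20.0,
    mapping_bias: float = 1.0,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Counts for an explicit panel of (snp_id, assay, rho) sites.

    Every site is heterozygous in ``n_individuals`` individuals — the panel
    conditions on heterozygosity because only het sites are testable;
    genotype sampling belongs to the genome-level simulator. Used for null
    calibration and power studies where the site inventory must be exact.
    """
    required = {"snp_id", "assay", "rho"}
    if not required <= set(pair_table.columns):
        raise ValueError(f"pair_table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    individuals = [f"S{i + 1:02d}" for i in range(n_individuals)]
    base = pair_table.loc[:, ["snp_id", "assay", "rho"]].reset_index(drop=True)
    size = coverage_size
    p_nb = size / (size + coverage_mean)
    pieces = []
    for individual in individuals:
        rho = base["rho"].to_numpy(dtype=float)
        p_ref_t, p_alt_t = target_success_probs(rho, mapping_bias)
        for target, p in (("reference", p_ref_t), ("alternative", p_alt_t)):
            n = rng.negative_binomial(size, p_nb, size=len(base))
            p_draw = p
            if overdispersion > 0:
                conc = 1.0 / overdispersion
                p_draw = rng.beta(np.clip(p * conc, 1e-9, None),
                                  np.clip((1.0 - p) * conc, 1e-9, None))
            ref = rng.binomial(n, p_draw)
            out = base[["snp_id", "assay"]].copy()
            out["individual"] = individual
            out["alignment_target"] = target
            out["ref_reads"] = ref
            out["alt_reads"] = n - ref
            pieces.append(out)
    counts = pd.concat(pieces, ignore_index=True)
    return counts[[
        "snp_id", "individual", "assay", "alignment_target", "ref_reads", "alt_reads",
    ]].sort_values(
        ["snp_id", "individual", "assay", "alignment_target"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# writing a study to disk in the pipeline's input formats
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Emit every generated table in the exact formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["snps"] = out / "snps.tsv"
    study.snps.to_csv(paths["snps"], sep="\t", index=False)

    paths["genes"] = out / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for row in study.genes.itertuples():
            if row.strand == "+":
                start, end = row.tss - 1, row.tss + 999
            else:
                start, end = row.tss - 1000, row.tss
            fh.write(f"{row.chrom}\t{start}\t{end}\t{row.symbol}\t0\t{row.strand}\n")

    paths["counts"] = out / "counts.tsv"
    study.counts.to_csv(paths["counts"], sep="\t", index=False)

    paths["peaks"] = out / "peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for row in study.peaks.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.protein}\n")

    for name, gene_set in study.gene_sets.items():
        key = f"gene_set_{name}"
        paths[key] = out / f"{name.lower()}.tsv"
        gene_set.table.to_csv(paths[key], sep="\t", index=False)

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths["truth_pairs"] = truth_dir / "imbalanced_pairs.tsv"
    study.truth.rho_map.to_csv(paths["truth_pairs"], sep="\t", index=False)
    paths["truth_rsnps"] = truth_dir / "planted_rsnps.tsv"
    pd.DataFrame({"snp_id": sorted(study.truth.planted_rsnps)}).to_csv(
        paths["truth_rsnps"], sep="\t", index=False
    )
    paths["truth_links"] = truth_dir / "planted_links.tsv"
    links_to_frame(study.truth.planted_links).to_csv(
        paths["truth_links"], sep="\t", index=False
    )
    paths["truth_genotypes"] = truth_dir / "genotypes.tsv"
    study.truth.genotypes.to_csv(paths["truth_genotypes"], sep="\t", index=False)
    paths["truth_promoter_map"] = truth_dir / "promoter_map.tsv"
    study.truth.promoter_map.to_csv(paths["truth_promoter_map"], sep="\t", index=False)
    return paths
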
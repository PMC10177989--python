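"""Allele-specific event calling with two concordant exact binomial tests.

At every heterozygous SNP the read counts over the two alleles are tested
against the symmetric null (ref-allele probability ``p0 = 0.5``) twice: once
on counts from the alignment to the reference genome and once on counts from
the alignment to the individual's alternative-reference sequence. Reference
mapping bias inflates the reference allele on the first target and the
alternative allele on the second, so a genuine allelic imbalance must show
the *same* direction on both targets while a bias artifact cannot. An
allele-specific expression (ASE, RNA) or binding (ASB, histone mark) event
is called only when both tests pass the adjusted-p and folded odds-ratio
thresholds with concordant direction.

Multiple testing is corrected with Benjamini–Hochberg, in separate families
for the RNA-seq and ChIP-seq tests (all histone marks pooled into one family
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import COUNT_KEY

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "snp_id", "individual", "assay",
    "ref_reads_reference", "alt_reads_reference",
    "ref_reads_alternative", "alt_reads_alternative",
    "p_reference", "p_alternative",
    "padj_reference", "padj_alternative",
    "or_reference", "or_alternative",
    "extreme_reference", "extreme_alternative",
    "direction_reference", "direction_alternative",
    "is_event",
]
EVENT_COLUMNS = [
    "snp_id", "individual", "assay", "event_class", "mark",
    "padj_reference", "padj_alternative",
    "or_reference", "or_alternative", "direction",
]


@dataclass(frozen=True)
class TestConfig:
    """Thresholds and options of the allelic-imbalance caller.

    Defaults are the conventional operating point for allelic-imbalance
    calling: folded odds ratio >= 1.5 and BH-adjusted p <= 0.1, null
    ref-allele probability 0.5. ``min_coverage`` (total reads per alignment
    target) is a pragmatic floor below which the exact test has essentially
    no power.
    """

    p0: float = 0.5
    or_threshold: float = 1.5
    padj_threshold: float = 0.1
    min_coverage: int = 10
    bh_family: str = "assay_class"  # or "per_mark"
    #: restrict the decision to one alignment target ("reference" or
    #: "alternative"); None = the dual concordant test. The single-target
    #: mode exists for bias studies, not for production calling.
    single_target: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must be in (0, 1)")
        if self.or_threshold < 1:
            raise ValueError("or_threshold must be >= 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.bh_family not in ("assay_class", "per_mark"):
            raise ValueError("bh_family must be 'assay_class' or 'per_mark'")
        if self.single_target not in (None, "reference", "alternative"):
            raise ValueError("single_target must be None, 'reference' or 'alternative'")


class CallOutcome(NamedTuple):
    """Full per-site test results plus the called events."""

    results: pd.DataFrame
    events: pd.DataFrame
    n_skipped_single_target: int
    n_low_coverage: int


def binomial_two_sided_p(k, n, p0: float = 0.5):
    """Exact two-sided binomial p-value by doubling the smaller tail.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` for ``X ~ Binomial(n, p0)``.
    Accepts scalars or arrays; returns the matching shape.
    """
    k_arr = np.asarray(k, dtype=np.int64)
    n_arr = np.asarray(n, dtype=np.int64)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    lower = stats.binom.cdf(k_arr, n_arr, p0)
    upper = stats.binom.sf(k_arr - 1, n_arr, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p.item() if np.isscalar(k) or np.ndim(k) == 0 else p


def folded_odds_ratio(ref_reads, alt_reads):
    """Fold the ref:alt count ratio above 1: ``max(r, 1/r)``.

    When one count is zero the ratio is undefined; the Haldane–Anscombe
    continuity constant 0.5 is added to both counts and the value is flagged
    extreme. Both counts zero raise.

    Returns ``(ratio, extreme_flag)``, scalars or arrays to match the input.
    """
    ref_arr = np.asarray(ref_reads, dtype=float)
    alt_arr = np.asarray(alt_reads, dtype=float)
    if np.any(ref_arr + alt_arr < 1):
        raise ValueError("at least one read required to form an odds ratio")
    extreme = (ref_arr == 0) | (alt_arr == 0)
    c = np.where(extreme, 0.5, 0.0)
    r = (ref_arr + c) / (alt_arr + c)
    folded = np.maximum(r, 1.0 / r)
    if np.isscalar(ref_reads) or np.ndim(ref_reads) == 0:
        return folded.item(), bool(extreme)
    return folded, extreme


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    out = np.full(ref.shape, "none", dtype=object)
    out[ref > alt] = "ref"
    out[ref < alt] = "alt"
    return out


def compute_test_results(counts: pd.DataFrame, config: TestConfig | None = None) -> CallOutcome:
    """Run both exact binomial tests at every testable site.

    ``counts`` must be pooled (unique on snp/individual/assay/target). Sites
    with only one alignment target are skipped with a logged count; sites
    under ``min_coverage`` on either target are excluded before the BH
    correction so the families contain only genuinely tested sites.
    """
    config = config or TestConfig()
    if counts.empty:
        logger.warning("no allelic counts supplied; returning empty results")
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return CallOutcome(empty, pd.DataFrame(columns=EVENT_COLUMNS), 0, 0)
    if counts.duplicated(COUNT_KEY).any():
        raise ValueError("counts contain duplicate keys; run pool_counts first")

    wide = counts.pivot_table(
        index=["snp_id", "individual", "assay"],
        columns="alignment_target",
        values=["ref_reads", "alt_reads"],
        aggfunc="first",
    )
    wide.columns = [f"{value}_{target}" for value, target in wide.columns]
    wide = wide.reset_index()
    for col in ("ref_reads_reference", "alt_reads_reference",
                "ref_reads_alternative", "alt_reads_alternative"):
        if col not in wide.columns:
            wide[col] = np.nan

    both = wide[[
        "ref_reads_reference", "alt_reads_reference",
        "ref_reads_alternative", "alt_reads_alternative",
    ]].notna().all(axis=1)
    n_skipped = int((~both).sum())
    if n_skipped:
        logger.info("skipped %d sites present on only one alignment target", n_skipped)
    wide = wide.loc[both].copy()

    cov_ref = wide["ref_reads_reference"] + wide["alt_reads_reference"]
    cov_alt = wide["ref_reads_alternative"] + wide["alt_reads_alternative"]
    covered = (cov_ref >= config.min_coverage) & (cov_alt >= config.min_coverage)
    n_low = int((~covered).sum())
    if n_low:
        logger.info("excluded %d sites under min_coverage=%d", n_low, config.min_coverage)
    wide = wide.loc[covered].reset_index(drop=True)
    if wide.empty:
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return CallOutcome(empty, pd.DataFrame(columns=EVENT_COLUMNS), n_skipped, n_low)

    for target in ("reference", "alternative"):
        ref = wide[f"ref_reads_{target}"].to_numpy(dtype=np.int64)
        alt = wide[f"alt_reads_{target}"].to_numpy(dtype=np.int64)
        wide[f"ref_reads_{target}"] = ref
        wide[f"alt_reads_{target}"] = alt
        wide[f"p_{target}"] = binomial_two_sided_p(ref, ref + alt, config.p0)
        folded, extreme = folded_odds_ratio(ref, alt)
        wide[f"or_{target}"] = folded
        wide[f"extreme_{target}"] = extreme
        wide[f"direction_{target}"] = _direction(ref, alt)

    family = (
        wide["assay"]
        if config.bh_family == "per_mark"
        else np.where(wide["assay"] == "RNA", "RNA", "ChIP")
    )
    wide["_family"] = family
    for target in ("reference", "alternative"):
        wide[f"padj_{target}"] = (
            wide.groupby("_family")[f"p_{target}"].transform(lambda p: bh_adjust(p.to_numpy()))
        )
    wide = wide.drop(columns="_family")

    if config.single_target is None:
        passes = np.ones(len(wide), dtype=bool)
        for target in ("reference", "alternative"):
            passes &= wide[f"padj_{target}"].to_numpy() <= config.padj_threshold
            passes &= wide[f"or_{target}"].to_numpy() >= config.or_threshold
        concordant = (
            wide["direction_reference"].to_numpy() == wide["direction_alternative"].to_numpy()
        ) & (wide["direction_reference"].to_numpy() != "none")
        wide["is_event"] = passes & concordant
    else:
        t = config.single_target
        wide["is_event"] = (
            (wide[f"padj_{t}"].to_numpy() <= config.padj_threshold)
            & (wide[f"or_{t}"].to_numpy() >= config.or_threshold)
            & (wide[f"direction_{t}"].to_numpy() != "none")
        )

    results = wide[RESULT_COLUMNS].copy()
    events = _events_from_results(results, config)
    return CallOutcome(results, events, n_skipped, n_low)


def _events_from_results(results: pd.DataFrame, config: TestConfig) -> pd.DataFrame:
    called = results.loc[results["is_event"]].copy()
    if called.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    called["event_class"] = np.where(called["assay"] == "RNA", "ASE", "ASB")
    called["mark"] = np.where(called["assay"] == "RNA", "", called["assay"])
    direction_col = (
        "direction_reference" if config.single_target != "alternative" else "direction_alternative"
    )
    called["direction"] = called[direction_col]
    return called[EVENT_COLUMNS].reset_index(drop=True)


def call_allelic_events(counts: pd.DataFrame, config: TestConfig | None = None) -> pd.DataFrame:
    """Call ASE/ASB events from pooled allelic counts.

    Convenience wrapper around :func:`compute_test_results` returning only
    the event table (one row per concordant significant site).
    """
    return compute_test_results(counts, config).events
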
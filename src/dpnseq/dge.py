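"""Digital differential expression between the two libraries.

Per-gene read counts (each read counted for at most one gene) are scaled to
reads per million (RPM); differential expression is the C5.2/HB4a RPM ratio
with zero counts replaced by 1, flagged at |log2| >= 2 (four-fold). The
Bayes Error Rate is the posterior probability, under independent conjugate
Beta models for the two per-library proportions, that the true ordering
contradicts the observed difference: min{P(p1<p2), P(p1>p2)}.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .align import AlignmentRecord
from .config import PipelineConfig

SAMPLES = ("HB4a", "C5.2")


def count_genes(
    tx_records: dict[str, list[AlignmentRecord]],
    read_library: dict[str, str | None],
    txdb: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Per-gene, per-library counts from transcript-space alignments.

    ``tx_records`` holds the records passing the transcript-DB thresholds;
    reads with significant alignments to more than one distinct gene are
    excluded, as are reads without a strict-mode library assignment.
    Counting is position-independent.
    """
    if not txdb:
        raise ValueError("transcript database is empty")
    genes = sorted({gid for gid, _ in txdb.values()})
    counts = {lib: {g: 0 for g in genes} for lib in SAMPLES}
    for rid, recs in tx_records.items():
        lib = read_library.get(rid)
        if lib not in SAMPLES:
            continue
        hit_genes = {txdb[r.chrom][0] for r in recs}
        if len(hit_genes) != 1:
            continue
        counts[lib][hit_genes.pop()] += 1
    df = pd.DataFrame(
        {"count_HB4a": counts["HB4a"], "count_C52": counts["C5.2"]}, index=genes
    )
    df.index.name = "gene_id"
    return df


def fold_change(
    counts: pd.DataFrame,
    totals: tuple[int, int] | None = None,
    log2_cutoff: float = 2.0,
) -> pd.DataFrame:
    """RPM, C5.2/HB4a log2 ratio (zero counts replaced by 1 before the
    ratio), and the differential flag at |log2| >= cutoff (inclusive)."""
    if totals is None:
        totals = (int(counts["count_HB4a"].sum()), int(counts["count_C52"].sum()))
    t1, t2 = totals
    if t1 <= 0 or t2 <= 0:
        raise ValueError("library totals must be positive")
    df = counts.copy()
    df["RPM_HB4a"] = df["count_HB4a"] / t1 * 1e6
    df["RPM_C52"] = df["count_C52"] / t2 * 1e6
    c1 = df["count_HB4a"].clip(lower=1)
    c2 = df["count_C52"].clip(lower=1)
    df["log2_ratio"] = np.log2((c2 / t2) / (c1 / t1))
    df["differential"] = df["log2_ratio"].abs() >= log2_cutoff
    return df


def bayes_error_rate(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    prior: tuple[float, float] = (1.0, 1.0),
    method: str = "quad",
    draws: int = 100_000,
    seed: int = 0,
) -> float:
    """min{P(p1<p2), P(p1>p2)} under independent Beta posteriors.

    With prior Beta(a,b), the posterior of each proportion is
    Beta(a+x, b+n-x); P(p1<p2) is computed by adaptive quadrature of
    f1(p) * (1 - F2(p)), or by Monte Carlo when method='mc'.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts exceed totals")
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior must be positive")
    a1, b1 = a + x1, b + n1 - x1
    a2, b2 = a + x2, b + n2 - x2
    if method == "mc":
        rng = np.random.default_rng(seed)
        p1 = rng.beta(a1, b1, draws)
        p2 = rng.beta(a2, b2, draws)
        p_less = float(np.mean(p1 < p2))
    else:
        d1 = stats.beta(a1, b1)
        d2 = stats.beta(a2, b2)
        lo = max(0.0, min(d1.ppf(1e-10), d2.ppf(1e-10)))
        hi = min(1.0, max(d1.isf(1e-10), d2.isf(1e-10)))
        p_less, _ = integrate.quad(
            lambda p: d1.pdf(p) * d2.sf(p), lo, hi, limit=200,
            points=[d1.mean(), d2.mean()],
        )
        p_less = min(max(p_less, 0.0), 1.0)
    return min(p_less, 1.0 - p_less)


def expression_table(
    counts: pd.DataFrame,
    config: PipelineConfig | None = None,
    totals: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Counts, RPM, log2 ratio, Bayes Error Rate and differential flag."""
    config = config or PipelineConfig()
    df = fold_change(counts, totals=totals, log2_cutoff=config.dge_fold_cutoff)
    if totals is None:
        totals = (int(counts["count_HB4a"].sum()), int(counts["count_C52"].sum()))
    bers = [
        bayes_error_rate(int(r.count_HB4a), totals[0], int(r.count_C52), totals[1],
                         prior=config.ber_prior)
        for r in df.itertuples()
    ]
    df["bayes_error_rate"] = bers
    return df


def as_enrichment(
    category_counts: dict[str, tuple[int, int]], totals: tuple[int, int]
) -> dict[str, float]:
    """Two-sided Fisher exact test per alternative-splicing category: event
    count vs library read total, one test per category."""
    t1, t2 = totals
    if t1 <= 0 or t2 <= 0:
        raise ValueError("library totals must be positive")
    out = {}
    for cat, (e1, e2) in category_counts.items():
        _, p = stats.fisher_exact([[e1, t1 - e1], [e2, t2 - e2]])
        out[cat] = float(p)
    return out


def rapamycin_response(fold_untreated: float | None, fold_treated: float | None) -> str:
    """'responsive' iff the treated fold-change decreases in magnitude or
    inverts sign relative to untreated; 'nd' when a Ct was undetermined."""
    if fold_untreated is None or fold_treated is None:
        return "nd"
    if isinstance(fold_untreated, float) and math.isnan(fold_untreated):
        return "nd"
    if isinstance(fold_treated, float) and math.isnan(fold_treated):
        return "nd"
    inverted = (fold_untreated > 0) != (fold_treated > 0)
    decreased = abs(fold_treated) < abs(fold_untreated)
    return "responsive" if (inverted or decreased) else "not_responsive"


def spearman_counts_vs_ct(counts, ct_values) -> tuple[float, float, bool]:
    """Spearman rho and two-sided p between read counts and qRT-PCR Ct
    values; the flag is True when rho is undefined (constant vector)."""
    x = np.asarray(counts, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("paired vectors of length >= 4 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"), True)
    rho, p = stats.spearmanr(x, y)
    return (float(rho), float(p), False)
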
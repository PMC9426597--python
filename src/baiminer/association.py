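"""Disease-group comparisons and bile-acid-ratio correlations.

Group differences in per-cluster CPM are tested with the two-sided
Mann-Whitney U (exact enumeration for small samples without ties, normal
approximation with tie correction otherwise), annotated with the
conventional significance stars.  Abundance/metabolite association uses
Spearman rank correlation of cluster CPM against the ratio of secondary
bile acids (DCA + LCA) to primary bile acids (CA + CDCA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .abundance import AbundanceProfile
from .io_formats import SampleMetadata

logger = logging.getLogger("baiminer")

EXACT_MAX_N = 12  # exact U-distribution enumeration up to this combined n


def stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    cluster_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: str  # {a>b, b>a, none}
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")
        if self.stars != stars(self.p_value):
            raise ValueError("stars inconsistent with p_value")


@dataclass(frozen=True)
class CorrelationResult:
    cluster_id: str
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1.0 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def ba_ratio(meta: SampleMetadata) -> float:
    """Secondary:primary bile-acid ratio, (DCA + LCA) / (CA + CDCA).

    Raises ``ValueError`` when concentrations are absent or the primary
    pool is zero; callers exclude such samples (with a log entry) rather
    than imputing.
    """
    ba = meta.ba_concentrations
    if ba is None:
        raise ValueError(f"sample {meta.sample_id}: no bile-acid concentrations")
    primary = ba["CA"] + ba["CDCA"]
    if primary <= 0:
        raise ValueError(f"sample {meta.sample_id}: zero primary bile-acid pool")
    return (ba["DCA"] + ba["LCA"]) / primary


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U of sample a, p-value).

    Exact when the combined sample is small (<= 12) and tie-free,
    otherwise normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= EXACT_MAX_N and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    profiles: Sequence[AbundanceProfile],
    metadata: Sequence[SampleMetadata],
    cluster_id: str,
    reference_group: str = "healthy",
    min_group_size: int = 3,
) -> list[GroupComparison]:
    """Each disease group against the reference group, per cluster CPM.

    Groups with fewer than ``min_group_size`` samples are skipped with a
    warning.  P-values are reported raw (no multiple-testing correction
    by default); apply :func:`benjamini_hochberg` separately if wanted.
    """
    groups: dict[str, list[float]] = {}
    by_sample = {p.sample_id: p for p in profiles}
    for meta in metadata:
        prof = by_sample.get(meta.sample_id)
        if prof is None or cluster_id not in prof.cpm:
            continue
        groups.setdefault(meta.group, []).append(prof.cpm[cluster_id])
    ref = groups.get(reference_group)
    if ref is None or len(ref) < min_group_size:
        logger.warning("compare_groups: reference group %r absent or too small", reference_group)
        return []
    out = []
    for group in sorted(groups):
        if group == reference_group:
            continue
        vals = groups[group]
        if len(vals) < min_group_size:
            logger.warning("compare_groups: group %r too small (n=%d), skipped", group, len(vals))
            continue
        u, p = mann_whitney(ref, vals)
        med_diff = float(np.median(ref) - np.median(vals))
        direction = "a>b" if med_diff > 0 else ("b>a" if med_diff < 0 else "none")
        out.append(
            GroupComparison(
                cluster_id=cluster_id,
                group_a=reference_group,
                group_b=group,
                n_a=len(ref),
                n_b=len(vals),
                u_statistic=u,
                p_value=p,
                direction=direction,
                stars=stars(p),
            )
        )
    return out


def spearman(
    abundance: Sequence[float], ratio: Sequence[float], cluster_id: str = "all"
) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value.

    Midranks handle ties; zero variance in either vector leaves rho
    undefined and raises ``ValueError``.
    """
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(ratio, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: rho undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(
        cluster_id=cluster_id,
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
    )


def correlation_table(
    profiles: Sequence[AbundanceProfile],
    metadata: Sequence[SampleMetadata],
    cluster_ids: Sequence[str],
) -> list[CorrelationResult]:
    """Per-cluster and pooled ("all") correlations against the BA ratio.

    Samples without a defined bile-acid ratio are excluded pairwise.
    """
    by_sample = {p.sample_id: p for p in profiles}
    pairs: list[tuple[AbundanceProfile, float]] = []
    for meta in metadata:
        prof = by_sample.get(meta.sample_id)
        if prof is None:
            continue
        try:
            r = ba_ratio(meta)
        except ValueError as exc:
            logger.info("correlation_table: excluded %s (%s)", meta.sample_id, exc)
            continue
        pairs.append((prof, r))
    ratios = [r for _, r in pairs]
    results = []
    total = [sum(p.cpm.get(c, 0.0) for c in cluster_ids) for p, _ in pairs]
    results.append(spearman(total, ratios, cluster_id="all"))
    for c in cluster_ids:
        vals = [p.cpm.get(c, 0.0) for p, _ in pairs]
        try:
            results.append(spearman(vals, ratios, cluster_id=c))
        except ValueError as exc:
            logger.warning("correlation_table: cluster %s skipped (%s)", c, exc)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (offered behind a flag; not applied by default)."""
    return list(stats.false_discovery_control(p_values, method="bh"))
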
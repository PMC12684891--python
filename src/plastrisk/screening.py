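"""Meta-analysis screening statistics and the data-sufficiency gate.

Covers ingestion frequency-of-occurrence tables, mortality-given-ingestion
rates, chi-squared / Fisher association tests, Kruskal-Wallis + Dunn rank
comparisons of loads across cause-of-death groups, the PERMANOVA on
Bray-Curtis dissimilarities of per-category plastic composition, and the
gate that decides whether a taxon-category combination has enough signal to
support a mortality model (at least five debris deaths, KD loads
significantly above KND loads, IND loads in between).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .core import EVENT_CAUSES, CauseOfDeath, PlasticCategory, Taxon
from .necropsy import NecropsyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SufficiencyVerdict",
    "frequency_of_occurrence",
    "mortality_given_ingestion",
    "association_test",
    "load_group_comparison",
    "data_sufficiency",
    "permanova_bray_curtis",
]

TOTAL = "TOTAL"


def frequency_of_occurrence(dataset: NecropsyDataset, taxon: Taxon) -> pd.Series:
    """Percent of individuals of ``taxon`` carrying >= 1 piece of each category.

    Includes a TOTAL entry (any category).  A binary measure: an individual
    either ingested the category or did not.
    """
    records = dataset.subset(taxon).records
    if not records:
        raise ValueError(f"no records for taxon {taxon.value}")
    n = len(records)
    out = {}
    for cat in PlasticCategory:
        out[cat.value] = 100.0 * sum(r.load_for(cat).piece_count > 0 for r in records) / n
    out[TOTAL] = 100.0 * sum(r.total_pieces() > 0 for r in records) / n
    return pd.Series(out, name=f"fo_{taxon.value}")


def mortality_given_ingestion(dataset: NecropsyDataset, taxon: Taxon) -> pd.DataFrame:
    """Among ingesters of each category: percent KD (and PD) with that category
    attributed.  Categories nobody ingested are absent, not zero."""
    records = dataset.subset(taxon).records
    if not records:
        raise ValueError(f"no records for taxon {taxon.value}")
    rows = {}
    for cat in PlasticCategory:
        ingesters = [r for r in records if r.load_for(cat).piece_count > 0]
        if not ingesters:
            continue
        kd = sum(
            r.cause_of_death is CauseOfDeath.KD and cat in r.death_attributed_categories
            for r in ingesters
        )
        pd_ = sum(
            r.cause_of_death is CauseOfDeath.PD and cat in r.death_attributed_categories
            for r in ingesters
        )
        rows[cat.value] = (100.0 * kd / len(ingesters), 100.0 * pd_ / len(ingesters))
    any_ingesters = [r for r in records if r.total_pieces() > 0]
    if any_ingesters:
        kd = sum(r.cause_of_death is CauseOfDeath.KD for r in any_ingesters)
        pd_ = sum(r.cause_of_death is CauseOfDeath.PD for r in any_ingesters)
        rows[TOTAL] = (100.0 * kd / len(any_ingesters), 100.0 * pd_ / len(any_ingesters))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["kd_pct", "pd_pct"])


def association_test(
    table, rule_config: dict | None = None
) -> tuple[str, float, float]:
    """Test association in a contingency table of counts.

    Fisher's exact test is used when any expected cell count falls below the
    configured cutoff (default 5) and the table is 2x2; otherwise Pearson's
    chi-squared.  Returns (test name, statistic, two-sided p).
    """
    cfg = dict(rule_config or {})
    cutoff = cfg.get("expected_cell_cutoff", 5.0)
    force = cfg.get("force")  # "fisher" | "chi2" | None
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: a zero margin")
    expected = stats.contingency.expected_freq(t)
    use_fisher = force == "fisher" or (force is None and np.any(expected < cutoff))
    if use_fisher and t.shape == (2, 2):
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return "fisher", float(odds), float(p)
    if use_fisher:
        warnings.warn(
            "expected-cell rule favors Fisher's exact but the table is larger "
            "than 2x2; falling back to Pearson chi-squared",
            RuntimeWarning,
        )
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return "chi2", float(chi2), float(p)


def _dunn_pairwise(groups: dict[str, np.ndarray], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's z-tests on rank means for all group pairs, with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    rank_means = {}
    start = 0
    for g in names:
        k = len(groups[g])
        rank_means[g] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    pairs = list(itertools.combinations(names, 2))
    raw_p, zs = [], []
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
            1.0 / na + 1.0 / nb
        )
        z = (rank_means[a] - rank_means[b]) / np.sqrt(var) if var > 0 else 0.0
        zs.append(z)
        raw_p.append(2 * stats.norm.sf(abs(z)))
    if p_adjust in ("holm", "bonferroni"):
        adj = multipletests(raw_p, method=p_adjust)[1]
    elif p_adjust in (None, "none"):
        adj = np.asarray(raw_p)
    else:
        raise ValueError(f"unknown p adjustment {p_adjust!r}")
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "z": zs,
            "p_raw": raw_p,
            "p_adjusted": adj,
        }
    )


def load_group_comparison(
    loads_by_group: dict[str, list[float] | np.ndarray],
    p_adjust: str = "holm",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H across cause-of-death groups plus Dunn pairwise z-tests.

    When every observation is identical the test is undefined; by convention
    H = 0, p = 1 (logged).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in loads_by_group.items() if len(v)}
    if len(groups) < 2:
        raise ValueError("at least two nonempty groups are required")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        logger.info("all loads identical across groups; H = 0, p = 1 by convention")
        dunn = _dunn_pairwise(groups, p_adjust)
        return 0.0, 1.0, dunn
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p), _dunn_pairwise(groups, p_adjust)


@dataclass
class SufficiencyVerdict:
    """Is a taxon-plastic-category combination data-sufficient for modeling?"""

    taxon: Taxon
    category: PlasticCategory | None  # None = TOTAL
    n_deaths: int
    kw_p: float
    dunn_p_kd_vs_knd: float
    ordered_medians: bool
    sufficient: bool
    reasons: list[str] = field(default_factory=list)


def data_sufficiency(
    dataset: NecropsyDataset,
    taxon: Taxon,
    category: PlasticCategory | None = None,
    min_deaths: int = 5,
    alpha: float = 0.05,
    p_adjust: str = "holm",
) -> SufficiencyVerdict:
    """Apply the modeling gate to one taxon-category combination.

    Requires (1) at least ``min_deaths`` debris deaths attributed to the
    category, (2) KD/PD piece loads significantly above KND loads (Dunn test,
    adjusted p < alpha, KD rank mean higher), and (3) median ordering
    KND <= IND <= KD (non-strict; trivially true when IND is empty).
    """
    records = dataset.subset(taxon).records
    cats = frozenset({category}) if category is not None else None

    def cat_pieces(r) -> int:
        return r.total_pieces(cats)

    def is_death(r) -> bool:
        return r.cause_of_death in EVENT_CAUSES and (
            category is None or category in r.death_attributed_categories
        )

    deaths = [r for r in records if is_death(r)]
    n_deaths = len(deaths)
    reasons: list[str] = []
    if n_deaths < min_deaths:
        reasons.append(f"fewer than {min_deaths} deaths ({n_deaths})")

    groups: dict[str, list[float]] = {"KND": [], "IND": [], "KD": []}
    for r in records:
        load = float(cat_pieces(r))
        if r.cause_of_death is CauseOfDeath.KND:
            groups["KND"].append(load)
        elif r.cause_of_death is CauseOfDeath.IND:
            groups["IND"].append(load)
        elif is_death(r):
            groups["KD"].append(load)

    kw_p = np.nan
    dunn_p = np.nan
    ordered = False
    if groups["KND"] and groups["KD"]:
        nonempty = {g: v for g, v in groups.items() if v}
        _, kw_p, dunn = load_group_comparison(nonempty, p_adjust=p_adjust)
        pair = dunn[
            ((dunn.group_a == "KD") & (dunn.group_b == "KND"))
            | ((dunn.group_a == "KND") & (dunn.group_b == "KD"))
        ]
        dunn_p = float(pair.p_adjusted.iloc[0])
        kd_higher = float(np.median(groups["KD"])) >= float(np.median(groups["KND"])) and (
            np.mean(stats.rankdata(np.concatenate([groups["KD"], groups["KND"]]))[: len(groups["KD"])])
            > np.mean(stats.rankdata(np.concatenate([groups["KD"], groups["KND"]]))[len(groups["KD"]) :])
        )
        if dunn_p >= alpha or not kd_higher:
            reasons.append(
                f"KD loads not significantly above KND (Dunn adjusted p = {dunn_p:.3g})"
            )
        med_knd = float(np.median(groups["KND"]))
        med_kd = float(np.median(groups["KD"]))
        if groups["IND"]:
            med_ind = float(np.median(groups["IND"]))
            ordered = med_knd <= med_ind <= med_kd
        else:
            ordered = med_knd <= med_kd
        if not ordered:
            reasons.append("median loads not ordered KND <= IND <= KD")
    else:
        reasons.append("missing KND or KD/PD group for load comparison")

    return SufficiencyVerdict(
        taxon=taxon,
        category=category,
        n_deaths=n_deaths,
        kw_p=float(kw_p),
        dunn_p_kd_vs_knd=float(dunn_p),
        ordered_medians=bool(ordered),
        sufficient=not reasons,
        reasons=reasons,
    )


def permanova_bray_curtis(
    composition_matrix,
    group_labels,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-way PERMANOVA on Bray-Curtis dissimilarities.

    ``composition_matrix`` holds nonnegative per-category quantities, one row
    per individual.  The pseudo-F compares among-group to within-group sums of
    squared dissimilarities; the p-value is (1 + #{permuted F >= observed}) /
    (1 + n_permutations) under random relabelling of rows.  With
    ``n_permutations="all"`` every label permutation is enumerated (small
    samples only) and the p-value is the exact proportion of permutations with
    F at least the observed value.
    """
    X = np.asarray(composition_matrix, dtype=float)
    labels = np.asarray(group_labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("composition matrix rows must match group labels")
    if np.any(X < 0):
        raise ValueError("composition quantities must be nonnegative")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("all-zero composition rows are undefined under Bray-Curtis")
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("at least two groups are required")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        raise ValueError("every group needs at least two individuals")

    d2 = squareform(pdist(X, metric="braycurtis")) ** 2
    n = X.shape[0]
    k = len(uniq)
    sst = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(assign: np.ndarray) -> float:
        ssw = 0.0
        for g in range(k):
            idx = np.flatnonzero(assign == g)
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        ssa = sst - ssw
        return (ssa / (k - 1)) / (ssw / (n - k))

    f_obs = pseudo_f(inv)
    tol = 1e-12 * max(1.0, abs(f_obs))
    if n_permutations == "all":
        if n > 9:
            raise ValueError("exhaustive enumeration is limited to 9 rows")
        perms = [
            pseudo_f(np.asarray(pm)) for pm in itertools.permutations(inv)
        ]
        p = float(np.mean(np.asarray(perms) >= f_obs - tol))
        return float(f_obs), p
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        if pseudo_f(rng.permutation(inv)) >= f_obs - tol:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + int(n_permutations))
    return float(f_obs), float(p)
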
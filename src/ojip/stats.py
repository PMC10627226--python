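"""Treatment-level statistics for agronomy-style reporting.

Per parameter and maturity group: one-way fixed-effects ANOVA across
treatment levels, Duncan's multiple range test with a compact letter
display ("means with the same letter are not significantly different"),
significance stars (*** p ≤ 0.001, ** p ≤ 0.01, * p ≤ 0.05), and a pooled
Pearson correlation matrix ordered by average-linkage clustering on 1 − r.

Duncan's procedure is implemented here from its definition (no package
call): means are sorted descending; the least significant range for a span
of p means uses the studentized-range quantile at protection level
1 − (1−α)^(p−1); a range is never declared significant when contained in a
non-significant wider range; letters come from the insert-and-absorb
compact-letter-display algorithm with "a" on the largest mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats as sps

from .errors import DesignError, DomainError
from .jip import report_round

#: Star thresholds, inclusive (p equal to a threshold earns the star).
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

#: Default parameter subset of the treatment report tables.
DEFAULT_TABLE_PARAMETERS = (
    "phi_Po", "phi_Do", "phi_Eo", "delta_Ro", "PI_abs", "rc_density",
)

#: Default parameter subset of the correlation heatmap.
DEFAULT_CORRELATION_PARAMETERS = (
    "phi_Po", "phi_Do", "psi_Eo", "phi_Eo", "delta_Ro", "phi_Ro",
    "TRo_RC", "ETo_RC", "REo_RC", "rc_density", "K_N", "K_P",
    "PI_abs", "SF_abs", "Fk_Fj",
)


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_error: int
    mse: float
    ss_between: float
    ss_within: float


@dataclass
class GroupStatsResult:
    """Per-parameter, per-maturity-group treatment comparison."""

    parameter: str
    maturity_group: str
    level_means: dict
    letters: dict
    p_value: float
    stars: str
    anova: AnovaResult


@dataclass
class CorrelationResult:
    parameters: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal, in `parameters` order
    ordering: list[int]  # cluster-derived permutation of `parameters`

    def ordered_frame(self) -> pd.DataFrame:
        names = [self.parameters[i] for i in self.ordering]
        m = self.matrix[np.ix_(self.ordering, self.ordering)]
        return pd.DataFrame(m, index=names, columns=names)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(values: Sequence[float], levels: Sequence) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA with MSE exposed for Duncan.

    Raises :class:`DesignError` for < 2 levels or a level with < 2
    observations, and :class:`DomainError` when within-group variance is
    zero everywhere (F undefined).
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    if not np.all(np.isfinite(values)):
        raise DomainError("ANOVA requires finite values")
    uniq = pd.unique(levels)
    if len(uniq) < 2:
        raise DesignError(f"ANOVA needs >= 2 levels, got {len(uniq)}")
    groups = [values[levels == u] for u in uniq]
    for u, g in zip(uniq, groups):
        if len(g) < 2:
            raise DesignError(f"level {u!r} has {len(g)} observation(s); need >= 2")
    n_total = len(values)
    k = len(uniq)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        raise DomainError("zero within-group variance everywhere: F undefined")
    msb, mse = ss_between / df_b, ss_within / df_w
    f_stat = msb / mse
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(float(f_stat), p, df_b, df_w, float(mse),
                       float(ss_between), float(ss_within))


def star_code(p_value: float) -> str:
    """Map a p-value to its significance stars ("ns" above 0.05)."""
    if not (0.0 <= p_value <= 1.0):
        raise DomainError(f"p-value outside [0, 1]: {p_value}")
    for threshold, stars in STAR_THRESHOLDS:
        if p_value <= threshold:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Duncan's multiple range test + compact letter display
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _duncan_quantile(span: int, df_error: int, alpha: float) -> float:
    # protection level 1 - (1-alpha)^(span-1) => upper quantile at its complement
    return float(sps.studentized_range.ppf((1 - alpha) ** (span - 1),
                                           span, df_error))


def least_significant_range(span: int, df_error: int, mse: float,
                            n_harmonic: float, alpha: float = 0.05) -> float:
    """Duncan's least significant range for a span of ``span`` ordered means."""
    return _duncan_quantile(span, df_error, alpha) * np.sqrt(mse / n_harmonic)


def _duncan_significant_pairs(
    means_desc: np.ndarray, df_error: int, mse: float, n_harmonic: float,
    alpha: float,
) -> set[tuple[int, int]]:
    """Index pairs (i<j, in descending-mean order) declared different.

    Ranges are scanned widest-first; a range whose spread does not exceed
    its least significant range — or that lies inside such a range — makes
    all its member pairs non-significant (Duncan's containment protection).
    """
    k = len(means_desc)
    nonsig: list[tuple[int, int]] = []
    sig: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        lsr = least_significant_range(span, df_error, mse, n_harmonic, alpha)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in nonsig):
                continue
            if means_desc[i] - means_desc[j] > lsr:
                sig.add((i, j))
            else:
                nonsig.append((i, j))
    return sig


def compact_letter_display(
    names_desc: Sequence, sig_pairs: set[tuple[int, int]]
) -> dict:
    """Insert-and-absorb letter assignment; "a" goes on the largest mean.

    Levels sharing any letter are not significantly different; levels
    sharing no letter are exactly the pairs in ``sig_pairs``.
    """
    k = len(names_desc)
    columns: list[set[int]] = [set(range(k))]
    for i, j in sorted(sig_pairs):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for new in (col - {j}, col - {i}):
                if not any(new <= other for other in columns):
                    columns.append(new)
    columns = [c for c in columns
               if not any(c < d for d in columns if d is not c)]
    columns.sort(key=min)  # letter order follows the top mean in each column
    letters: dict = {name: "" for name in names_desc}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for i in sorted(col):
            letters[names_desc[i]] += ch
    return letters


def duncan_mrt(
    level_means: Mapping,
    n_per_level: Mapping | int,
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> dict:
    """Duncan's multiple range test: compact letters per treatment level.

    ``n_per_level`` may be a single (balanced) count or a mapping; when
    unbalanced, the harmonic mean of the counts is used.
    """
    if df_error <= 0:
        raise DesignError(f"df_error must be > 0, got {df_error}")
    if not (0 < alpha < 1):
        raise DesignError(f"alpha must be in (0, 1), got {alpha}")
    names = sorted(level_means, key=lambda n: -level_means[n])
    means_desc = np.array([level_means[n] for n in names], dtype=float)
    if isinstance(n_per_level, Mapping):
        counts = np.array([n_per_level[n] for n in names], dtype=float)
        n_h = len(counts) / (1.0 / counts).sum()
    else:
        n_h = float(n_per_level)
    sig = _duncan_significant_pairs(means_desc, df_error, mse, n_h, alpha)
    return compact_letter_display(names, sig)


# ---------------------------------------------------------------------------
# treatment report tables
# ---------------------------------------------------------------------------

def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def summarize_treatment_table(
    params: pd.DataFrame,
    axis: str = "temperature",
    columns: Sequence[str] = DEFAULT_TABLE_PARAMETERS,
    alpha: float = 0.05,
    use_replicate_means: bool = True,
) -> tuple[pd.DataFrame, list[GroupStatsResult]]:
    """Per-maturity-group treatment comparison table with Duncan letters.

    ``params`` is the per-trace JIP parameter table with metadata columns.
    Within each maturity group the chosen parameters are compared across the
    treatment levels of ``axis`` ("temperature" or "day_length"): replicate
    (pot) means are the ANOVA observations by default, treating the repeated
    measurements within a pot as pseudo-replicates to be averaged first
    (``use_replicate_means=False`` switches to all raw measurements).

    Returns the formatted report frame — level means rounded to report
    precision with letters attached, plus a significance-star row and a
    p-value row per group — and the underlying :class:`GroupStatsResult`
    objects.
    """
    level_col = "temperature" if axis == "temperature" else "day_length_h"
    if level_col not in params.columns:
        raise DesignError(f"parameter table lacks a {level_col!r} column")
    missing = [c for c in columns if c not in params.columns]
    if missing:
        raise DesignError(f"parameter table lacks column(s): {missing}")

    results: list[GroupStatsResult] = []
    rows: list[dict] = []
    for mg, sub in params.groupby("maturity_group", sort=False):
        levels_order = list(pd.unique(sub[level_col]))
        if len(levels_order) < 2:
            raise DesignError(
                f"maturity group {mg}: ANOVA undefined with a single level"
            )
        if use_replicate_means:
            obs = (sub.groupby([level_col, "replicate"], sort=False)[list(columns)]
                   .mean().reset_index())
        else:
            obs = sub[[level_col, "replicate"] + list(columns)]
        per_param: dict[str, GroupStatsResult] = {}
        for param in columns:
            cell_counts = obs.groupby(level_col)[param].count()
            for lv in levels_order:
                if cell_counts.get(lv, 0) < 2:
                    raise DesignError(
                        f"cell (maturity group {mg}, level {lv}) has "
                        f"< 2 observations for {param}"
                    )
            an = one_way_anova(obs[param].to_numpy(), obs[level_col].to_numpy())
            means = obs.groupby(level_col)[param].mean().to_dict()
            counts = cell_counts.to_dict()
            letters = duncan_mrt(means, counts, an.mse, an.df_error, alpha)
            res = GroupStatsResult(
                parameter=param, maturity_group=str(mg), level_means=means,
                letters=letters, p_value=an.p_value,
                stars=star_code(an.p_value), anova=an,
            )
            per_param[param] = res
            results.append(res)
        for lv in levels_order:
            row = {"maturity_group": mg, "level": lv}
            for param in columns:
                r = per_param[param]
                row[param] = (
                    f"{report_round(param, r.level_means[lv]):.{3 if param == 'phi_Po' else 2}f}"
                    f"{r.letters[lv]}"
                )
            rows.append(row)
        rows.append({"maturity_group": mg, "level": "Significance",
                     **{p: per_param[p].stars for p in columns}})
        rows.append({"maturity_group": mg, "level": "p-value",
                     **{p: _format_p(per_param[p].p_value) for p in columns}})
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(
    params: pd.DataFrame,
    subset: Sequence[str] = DEFAULT_CORRELATION_PARAMETERS,
    method: str = "pearson",
) -> CorrelationResult:
    """Pooled pairwise correlations of JIP parameters, cluster-ordered.

    Observations are pooled across all treatments and maturity groups.
    Constant columns are dropped with a warning (their correlation is
    undefined); rows/columns are permuted by average-linkage clustering on
    the distance 1 − r so strongly associated parameter blocks sit together.
    """
    cols = [c for c in subset if c in params.columns]
    if len(params) < 3:
        raise DesignError("correlation needs >= 3 observations")
    data = params[cols].astype(float)
    constant = [c for c in cols if float(data[c].std()) == 0.0 or data[c].isna().all()]
    if constant:
        warnings.warn(
            f"dropping constant column(s) from correlation: {constant}",
            stacklevel=2,
        )
        cols = [c for c in cols if c not in constant]
        data = data[cols]
    if len(cols) < 2:
        raise DesignError("correlation needs >= 2 non-constant parameters")
    corr = data.corr(method=method).to_numpy()
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(len(cols), k=1)]
    link = sch.linkage(condensed, method="average")
    ordering = list(sch.leaves_list(sch.optimal_leaf_ordering(link, condensed)))
    return CorrelationResult(parameters=list(cols), matrix=corr,
                             ordering=ordering)


def plot_correlation_heatmap(result: CorrelationResult, path) -> None:
    """Render the cluster-ordered correlation matrix as a diverging heatmap.

    Brown–teal diverging scale: teal for positive, brown for negative
    correlations, brighter toward zero.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    frame = result.ordered_frame()
    fig, ax = plt.subplots(figsize=(0.5 * len(frame) + 2,) * 2)
    sns.heatmap(frame, cmap="BrBG", vmin=-1, vmax=1, center=0, square=True,
                ax=ax, cbar_kws={"label": "Pearson r"})
    ax.set_title("JIP parameter correlations (cluster-ordered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
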
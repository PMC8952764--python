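"""One-way ANOVA with Fisher's protected LSD and compact letter display.

Dose-mortality tables carry replicate counts of dead larvae per dose group
(replicate-level mortality is analysed as a plain percentage, 100*dead/n;
an arcsine-square-root transform is available as an option but is off by
default).  Means are separated only after a significant omnibus F test
(protected LSD): pair (i, j) differs when

    |mean_i - mean_j| > t(1 - alpha/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j))

and the resulting partition is summarised with insert-and-absorb compact
letters — groups sharing any letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "MORTALITY_COLUMNS",
    "group_summaries",
    "one_way_anova",
    "fisher_lsd",
    "AnovaLsdResult",
    "compact_letter_display",
]

MORTALITY_COLUMNS = (
    "dose",
    "experiment",
    "replicate",
    "n_larvae",
    "dead",
    "timepoint",
)


def validate_mortality_table(table: pd.DataFrame) -> None:
    missing = [c for c in MORTALITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mortality table lacks columns {missing}")
    if ((table["dead"] < 0) | (table["dead"] > table["n_larvae"])).any():
        raise ValueError("dead counts must satisfy 0 <= dead <= n_larvae")


def group_summaries(
    table: pd.DataFrame, timepoint: float
) -> pd.DataFrame:
    """Per-dose mean mortality % and sample SD at one observation time.

    Replicate-level mortality is ``100 * dead / n_larvae``; experiments are
    pooled as replicates (the experiment label is retained in the input but
    not modelled).
    """
    validate_mortality_table(table)
    sub = table.loc[table["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no rows at timepoint {timepoint!r}")
    pct = 100.0 * sub["dead"] / sub["n_larvae"]
    out = (
        pd.DataFrame({"dose": sub["dose"], "mortality_pct": pct})
        .groupby("dose", sort=True)["mortality_pct"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def _arcsine(pcts: np.ndarray) -> np.ndarray:
    return np.degrees(np.arcsin(np.sqrt(np.clip(pcts, 0, 100) / 100.0)))


def one_way_anova(
    groups: list[np.ndarray],
) -> tuple[float, float, int, int, float]:
    """Between/within decomposition: returns (F, p, df_between, df_within, MSE).

    Identical groups give F = 0, p = 1; each group needs >= 2 replicates.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 replicates")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    mse = ss_within / df_within
    if mse == 0.0:
        # all-constant groups: no variation at all -> F defined as 0 when the
        # group means coincide, infinite otherwise
        if ss_between == 0.0:
            return 0.0, 1.0, df_between, df_within, 0.0
        return float("inf"), 0.0, df_between, df_within, 0.0
    f_stat = (ss_between / df_between) / mse
    p = float(scipy.stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p, df_between, df_within, float(mse)


def compact_letter_display(
    labels: list, significant: np.ndarray
) -> dict:
    """Insert-and-absorb compact letters for a pairwise significance matrix.

    ``significant[i, j]`` is True when groups i and j differ.  The result
    maps each label to its letter string; groups share a letter iff they are
    not significantly different.  Deterministic in label order.
    """
    n = len(labels)
    sets: list[set[int]] = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if not significant[i, j]:
                continue
            for s in [s for s in sets if i in s and j in s]:
                sets.remove(s)
                sets.extend(c for c in (s - {i}, s - {j}) if c)
            # absorb: drop duplicates and sets contained in another set
            uniq: list[set[int]] = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = [s for s in uniq if not any(s < t for t in uniq)]
    # order letter sets by the smallest member index for stable output
    sets.sort(key=lambda s: min(s))
    letters = {lab: "" for lab in labels}
    for letter_idx, s in enumerate(sets):
        letter = chr(ord("a") + letter_idx)
        for i in sorted(s):
            letters[labels[i]] += letter
    return letters


@dataclass
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    alpha: float
    lsd_value: float
    group_means: dict = field(default_factory=dict)
    significant: pd.DataFrame | None = None
    letter_groups: dict = field(default_factory=dict)

    @property
    def anova_significant(self) -> bool:
        return self.p_value < self.alpha


def fisher_lsd(
    groups: dict,
    alpha: float = 0.05,
    arcsine_transform: bool = False,
) -> AnovaLsdResult:
    """Protected Fisher LSD over labelled replicate vectors.

    ``groups`` maps a label (e.g. a dose) to its replicate values.  If the
    omnibus ANOVA is not significant at ``alpha`` every group shares one
    letter (documented behaviour, not an error).  Unbalanced group sizes are
    handled through per-pair standard errors; ``lsd_value`` is reported for
    the harmonic-mean group size.
    """
    labels = list(groups.keys())
    vectors = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if arcsine_transform:
        vectors = [_arcsine(v) for v in vectors]
    f_stat, p, dfb, dfw, mse = one_way_anova(vectors)
    means = {lab: float(v.mean()) for lab, v in zip(labels, vectors)}
    ns = {lab: len(v) for lab, v in zip(labels, vectors)}
    t_crit = float(scipy.stats.t.ppf(1 - alpha / 2, dfw))
    n_harm = len(labels) / sum(1.0 / ns[lab] for lab in labels)
    lsd_value = t_crit * np.sqrt(mse * 2.0 / n_harm)
    k = len(labels)
    sig = np.zeros((k, k), dtype=bool)
    if p < alpha:
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1.0 / ns[labels[i]] + 1.0 / ns[labels[j]]))
                diff = abs(means[labels[i]] - means[labels[j]])
                sig[i, j] = sig[j, i] = diff > t_crit * se
    letters = compact_letter_display(labels, sig)
    return AnovaLsdResult(
        f_statistic=f_stat,
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        mse=mse,
        alpha=alpha,
        lsd_value=float(lsd_value),
        group_means=means,
        significant=pd.DataFrame(sig, index=labels, columns=labels),
        letter_groups=letters,
    )


def mortality_lsd(
    table: pd.DataFrame,
    timepoint: float,
    alpha: float = 0.05,
    arcsine_transform: bool = False,
) -> AnovaLsdResult:
    """ANOVA + LSD over per-dose replicate mortality percentages."""
    validate_mortality_table(table)
    sub = table.loc[table["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no rows at timepoint {timepoint!r}")
    groups = {
        dose: (100.0 * grp["dead"] / grp["n_larvae"]).to_numpy()
        for dose, grp in sub.groupby("dose", sort=True)
    }
    return fisher_lsd(groups, alpha=alpha, arcsine_transform=arcsine_transform)
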
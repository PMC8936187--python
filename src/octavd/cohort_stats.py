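"""Longitudinal sector-design analysis of vessel-density tables.

The study design is within-eye paired: each operated eye contributes one
implant sector (the stent spans ~90 deg of Schlemm's canal) and two fixed
opposing control sectors without the implant, chosen once and kept
identical at every visit. Follow-up VD is compared to baseline with the
Wilcoxon signed-rank test per visit, and across the whole follow-up with
the Friedman test on complete cases; mean differences carry paired-t 95%
confidence intervals. Significance is 0.05 with no multiplicity
adjustment (each test is reported as-is; the report flags this).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig
from .types import SECTOR_ORDER, TestResult

__all__ = [
    "SectorDesign",
    "assign_controls",
    "select_index_sector",
    "wilcoxon_signed_rank",
    "friedman_statistic",
    "friedman_test",
    "serial_analysis",
    "SerialReport",
]

#: Fixed opposing-control mapping used for every implant location.
CONTROL_MAP: Dict[str, Tuple[str, str]] = {
    "superior_nasal": ("inferior", "temporal"),
    "inferior_nasal": ("superior", "temporal"),
    "inferior_temporal": ("superior", "nasal"),
}


@dataclass(frozen=True)
class SectorDesign:
    """One eye's frozen sector assignment: implant sector + two controls.

    Frozen by construction — the same sectors are compared at every visit.
    """

    implant_sector: str
    control_sectors: Tuple[str, str]

    def __post_init__(self) -> None:
        if self.implant_sector in self.control_sectors:
            raise ValueError("implant sector cannot be its own control")
        if len(set(self.control_sectors)) != 2:
            raise ValueError("exactly two distinct control sectors required")

    @classmethod
    def for_implant(cls, implant_sector: str) -> "SectorDesign":
        return cls(implant_sector, assign_controls(implant_sector))


def assign_controls(implant_sector: str) -> Tuple[str, str]:
    """The two opposing control sectors for an implant sector (fixed mapping)."""
    try:
        return CONTROL_MAP[implant_sector]
    except KeyError:
        raise ValueError(
            f"no control mapping for sector {implant_sector!r}; "
            f"valid implant sectors: {sorted(CONTROL_MAP)}"
        ) from None


def select_index_sector(
    baseline_vd: Mapping[str, float], candidates: Optional[Sequence[str]] = None
) -> str:
    """Pick the candidate sector with the highest baseline VD.

    Higher-VD sectors give more reliable signal, so the index (implant-arc)
    sector followed over time is the baseline-VD argmax. Exact ties break
    by canonical sector order; the selection is then frozen for all later
    visits.
    """
    candidates = list(candidates) if candidates is not None else list(baseline_vd)
    if not candidates:
        raise ValueError("no candidate sectors")
    missing = [c for c in candidates if c not in baseline_vd]
    if missing:
        raise ValueError(f"missing baseline VD for candidate sectors: {missing}")
    order = {s: i for i, s in enumerate(SECTOR_ORDER)}
    return max(candidates, key=lambda s: (baseline_vd[s], -order.get(s, len(order))))


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------


def wilcoxon_signed_rank(
    baseline: Sequence[float],
    followup: Sequence[float],
    zero_method: str = "wilcox",
    exact_cutoff: int = 15,
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test of follow-up vs baseline.

    Differences are follow-up minus baseline. Zero differences are dropped
    (classic treatment; ``zero_method="pratt"`` keeps them in the ranking).
    The p-value is exact — the full 2^n sign-flip distribution of the
    positive-rank sum, midranks for tied |differences| — for up to
    ``exact_cutoff`` informative pairs, else a normal approximation with
    tie and continuity corrections. The mean difference and its paired-t
    95% CI are computed over *all* pairs.
    """
    base = np.asarray(baseline, dtype=float)
    fup = np.asarray(followup, dtype=float)
    if base.shape != fup.shape or base.ndim != 1:
        raise ValueError("baseline and followup must be 1-D arrays of equal length")
    if base.size == 0:
        raise ValueError("no pairs supplied")
    d = fup - base

    mean_diff = float(d.mean())
    ci = _paired_t_ci(d)

    nz = d[d != 0]
    n_inf = nz.size
    if n_inf == 0:
        # all differences zero: no evidence either way
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, 0, mean_diff, ci, n_excluded=d.size
        )

    if n_inf <= exact_cutoff and zero_method == "wilcox":
        stat, p = _wilcoxon_exact(nz)
    else:
        res = sps.wilcoxon(
            d,
            zero_method=zero_method,
            correction=True,
            alternative="two-sided",
            method="approx",
        )
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        "wilcoxon_signed_rank",
        stat,
        float(min(p, 1.0)),
        int(n_inf),
        mean_diff,
        ci,
        n_excluded=int(d.size - n_inf),
    )


def _wilcoxon_exact(nz: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided p over all 2^n equiprobable sign assignments.

    The positive-rank sum W+ is symmetric about sum(ranks)/2 under the
    null, so the two-sided p is the probability of a deviation from the
    center at least as large as observed. Midranks make this valid under
    tied |differences| too.
    """
    n = nz.size
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    center = float(ranks.sum()) / 2.0
    # all 2^n sign assignments, vectorized: bit j of i selects rank j
    signs = (
        np.arange(2**n)[:, None] >> np.arange(n)[None, :]
    ) & 1
    sums = signs @ ranks
    p = float(np.mean(np.abs(sums - center) >= abs(w_plus - center) - 1e-12))
    return w_plus, p


def _paired_t_ci(d: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    n = d.size
    m = float(d.mean())
    if n < 2:
        return (m, m)
    se = float(d.std(ddof=1)) / math.sqrt(n)
    if se == 0:
        return (m, m)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, n - 1))
    return (m - tcrit * se, m + tcrit * se)


# --------------------------------------------------------------------------
# Friedman
# --------------------------------------------------------------------------


def friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for an n-blocks x k-treatments matrix.

    Within-block midranks; chi2 = (12/(n k (k+1)) sum_j R_j^2 - 3 n (k+1)) / C
    with C the standard tie correction. Returns 0 when every block is
    entirely tied (C = 0).
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * (k**3 - k))
    if c <= 0:
        return 0.0
    return chisq / c


def friedman_test(
    matrix,
    method: str = "auto",
    max_enumeration: int = 20000,
    n_resamples: int = 20000,
    seed: int = 0,
) -> TestResult:
    """Friedman test over an eyes x visits VD matrix (complete blocks only).

    Rows containing NaN (eyes missing a visit) are excluded and counted in
    ``n_excluded``. ``method``: "exact" enumerates every within-block
    permutation (feasible when k!^n <= ``max_enumeration``), "chisq" uses
    the chi-square approximation with tie correction, "sampled" draws
    ``n_resamples`` random within-block permutations, "auto" picks exact
    when affordable else chisq.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    complete = ~np.isnan(m).any(axis=1)
    n_excluded = int((~complete).sum())
    m = m[complete]
    n, k = m.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete blocks, got {n}")
    if k < 3:
        raise ValueError(f"need >= 3 treatments (visits), got {k}")

    obs = friedman_statistic(m)
    if method == "auto":
        method = "exact" if math.factorial(k) ** n <= max_enumeration else "chisq"

    if method == "chisq":
        p = float(sps.chi2.sf(obs, k - 1)) if obs > 0 else 1.0
    elif method in ("exact", "sampled"):
        # permuting values within a block only permutes that block's ranks,
        # so the tie correction is permutation-invariant: precompute ranks
        # once and evaluate the statistic from column rank sums
        ranks = np.apply_along_axis(sps.rankdata, 1, m)
        correction = _tie_correction(m)
        if correction <= 0:
            p = 1.0
        elif method == "exact":
            perms = list(itertools.permutations(range(k)))
            count = hits = 0
            for combo in itertools.product(perms, repeat=n):
                rj = np.stack(
                    [ranks[i, list(pi)] for i, pi in enumerate(combo)]
                ).sum(axis=0)
                stat = _chisq_from_colsums(rj, n, k) / correction
                count += 1
                if stat >= obs - 1e-9:
                    hits += 1
            p = hits / count
        else:
            rng = np.random.default_rng(seed)
            idx = rng.random((n_resamples, n, k)).argsort(axis=-1)
            permuted = np.take_along_axis(
                np.broadcast_to(ranks, (n_resamples, n, k)), idx, axis=-1
            )
            rj = permuted.sum(axis=1)
            stats = _chisq_from_colsums_batch(rj, n, k) / correction
            p = float((np.count_nonzero(stats >= obs - 1e-9) + 1) / (n_resamples + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult("friedman", float(obs), float(p), int(n), n_excluded=n_excluded)


def _tie_correction(m: np.ndarray) -> float:
    n, k = m.shape
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    return 1.0 - ties / (n * (k**3 - k))


def _chisq_from_colsums(rj: np.ndarray, n: int, k: int) -> float:
    return 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)


def _chisq_from_colsums_batch(rj: np.ndarray, n: int, k: int) -> np.ndarray:
    return 12.0 / (n * k * (k + 1)) * (rj**2).sum(axis=-1) - 3.0 * n * (k + 1)


# --------------------------------------------------------------------------
# Serial (longitudinal) analysis
# --------------------------------------------------------------------------


@dataclass
class SerialReport:
    """Per-group longitudinal results: summary table plus JSON-able report."""

    summary: pd.DataFrame
    report: dict

    def to_json_dict(self) -> dict:
        return self.report


def _group_pivot(df: pd.DataFrame, visits: Sequence[str]) -> pd.DataFrame:
    pivot = df.pivot_table(index="eye_id", columns="visit", values="vd", aggfunc="mean")
    return pivot.reindex(columns=[v for v in visits if v in pivot.columns])


def serial_analysis(
    cohort: pd.DataFrame,
    layer: str = "episcleral",
    cfg: Optional[StatsConfig] = None,
    friedman_method: str = "chisq",
) -> SerialReport:
    """Implant-vs-control longitudinal analysis of a long-format VD table.

    Expects columns eye_id, sector, layer, visit, implant, vd. Implant
    sectors form one group; each eye's two control sectors are ordered
    canonically and analyzed as two separate control groups (mirroring the
    two-control design). Per group: Wilcoxon signed-rank of every
    follow-up visit vs baseline (pairing strictly within eye), Friedman
    over the configured visit set on complete cases, and mean differences
    with paired-t 95% CIs. No multiplicity adjustment is applied.
    """
    cfg = cfg or StatsConfig()
    cfg.validate()
    df = cohort[cohort["layer"] == layer].copy()
    if df.empty:
        raise ValueError(f"no records for layer {layer!r}")
    visits = list(cfg.visits) if cfg.visits else _visits_in_order(df["visit"])
    baseline = cfg.baseline_visit
    if baseline not in visits:
        raise ValueError(f"baseline visit {baseline!r} absent from the table")
    followups = [v for v in visits if v != baseline]

    order = {s: i for i, s in enumerate(SECTOR_ORDER)}
    groups: Dict[str, pd.DataFrame] = {"implant": df[df["implant"]]}
    ctrl = df[~df["implant"]].copy()
    if not ctrl.empty:
        ctrl["_rank"] = (
            ctrl.sort_values("sector", key=lambda s: s.map(order))
            .groupby(["eye_id", "visit"])
            .cumcount()
        )
        # stable within-eye ordering: same sector keeps the same slot at every visit
        slot = (
            ctrl.groupby(["eye_id", "sector"])["_rank"].first().rename("_slot")
        )
        ctrl = ctrl.join(slot, on=["eye_id", "sector"])
        for i in (0, 1):
            groups[f"control_{i + 1}"] = ctrl[ctrl["_slot"] == i]

    summary_rows: List[dict] = []
    report: dict = {
        "layer": layer,
        "baseline": baseline,
        "visits": visits,
        "alpha": cfg.alpha,
        "multiplicity_adjustment": "none",
        "groups": {},
    }
    for name, g in groups.items():
        if g.empty:
            continue
        pivot = _group_pivot(g, visits)
        grp: dict = {"wilcoxon_vs_baseline": {}, "per_visit": {}}
        for visit in visits:
            vals = pivot[visit].dropna() if visit in pivot else pd.Series(dtype=float)
            row = {
                "group": name,
                "visit": visit,
                "n": int(vals.size),
                "mean_vd": float(vals.mean()) if vals.size else float("nan"),
                "sd_vd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "p_value": float("nan"),
                "mean_difference": float("nan"),
                "ci95_low": float("nan"),
                "ci95_high": float("nan"),
            }
            grp["per_visit"][visit] = {
                "n": row["n"],
                "mean_vd": row["mean_vd"],
                "sd_vd": row["sd_vd"],
            }
            if visit in followups and visit in pivot.columns:
                paired = pivot[[baseline, visit]].dropna()
                if len(paired) >= 1:
                    res = wilcoxon_signed_rank(
                        paired[baseline].to_numpy(),
                        paired[visit].to_numpy(),
                        zero_method=cfg.zero_method,
                        exact_cutoff=cfg.exact_cutoff,
                    )
                    row.update(
                        p_value=res.p_value,
                        mean_difference=res.mean_difference,
                        ci95_low=res.ci95[0],
                        ci95_high=res.ci95[1],
                    )
                    grp["wilcoxon_vs_baseline"][visit] = res.to_dict()
            summary_rows.append(row)

        fried_cols = [v for v in visits if v in pivot.columns]
        if len(fried_cols) >= 3 and len(pivot[fried_cols].dropna()) >= 3:
            fres = friedman_test(pivot[fried_cols].to_numpy(), method=friedman_method)
            grp["friedman"] = fres.to_dict()
        report["groups"][name] = grp

    return SerialReport(summary=pd.DataFrame(summary_rows), report=report)


def _visits_in_order(series: pd.Series) -> List[str]:
    seen: List[str] = []
    known = [v for v in series.unique()]
    # prefer the canonical schedule order where applicable
    from .types import VISIT_ORDER

    for v in VISIT_ORDER:
        if v in known:
            seen.append(v)
    for v in known:
        if v not in seen:
            seen.append(v)
    return seen
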
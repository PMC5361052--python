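"""Factorial experiment grid, summary table and paired winner rule.

The grid crosses synthetic setups x 12 leads x artifact realizations x SNR
levels x methods (the five filters plus a mandatory no-filter condition).
One artifact realization is drawn per (setup, lead, realization) cell and
reused across all SNR levels — only the scaling constant changes.  Per-cell
seeds derive from the master seed through ``SeedSequence`` spawn keys, so any
cell can be reproduced in isolation and reruns are bit-identical apart from
the wall-clock timing column.

Summaries report median and interquartile range per (method, criterion), and
the winner of a criterion is the best-median method provided its paired
Wilcoxon signed-rank comparison against *every* other method is significant;
the maximum pairwise p-value is reported, and the winner flag requires
max p < alpha (0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import BaselineSpec, corrupt, draw_realization, render, scale_to_snr
from .errors import ContractError, InvalidParameterError
from .filters import FILTERS, FilterOutput, apply_filter
from .metrics import correlation_coefficient, kp_deviation, l_operator, locate_kp, trim_boundaries
from .synthetic import N_LEADS, generate_setup_grid

__all__ = [
    "SNR_LEVELS_DB",
    "METRIC_COLUMNS",
    "ExperimentConfig",
    "SummaryTable",
    "run_grid",
    "summarize",
    "wilcoxon_signed_rank",
    "determine_winner",
]

logger = logging.getLogger(__name__)

SNR_LEVELS_DB = (-10.0, -3.0, 0.0, 3.0, 10.0, 20.0)

#: Frozen column order of the metric-row table.
METRIC_COLUMNS = [
    "record_id", "lead", "realization", "snr_db", "filter",
    "cc", "l_op", "dkp", "elapsed", "status",
]

#: Criteria: column, whether larger is better, and how the winner is chosen.
CRITERIA = {
    "cc": {"column": "cc", "higher_is_better": True, "absolute": False},
    "l_op": {"column": "l_op", "higher_is_better": True, "absolute": False},
    "dkp": {"column": "dkp", "higher_is_better": False, "absolute": True},
    "elapsed": {"column": "elapsed", "higher_is_better": False, "absolute": False},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition.  The full study used 765 setups x 12 leads x 100
    realizations x 6 SNR levels = 5,508,000 corrupted signals."""

    n_setups: int = 765
    n_realizations: int = 100
    snr_levels_db: tuple = SNR_LEVELS_DB
    filters: tuple = tuple(FILTERS)
    master_seed: int = 0
    duration: float = 100.0
    trim_margin: float = 1.0
    alternative: str = "greater"  # directional winner test; "two-sided" available
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_setups <= 0 or self.n_realizations <= 0:
            raise InvalidParameterError("grid dimensions must be positive")
        unknown = set(self.filters) - set(FILTERS)
        if unknown:
            raise InvalidParameterError(f"unknown filters: {sorted(unknown)}")

    @property
    def n_leads(self) -> int:
        return N_LEADS

    @property
    def grid_size(self) -> int:
        """Number of corrupted signals (one per setup/lead/realization/SNR)."""
        return self.n_setups * N_LEADS * self.n_realizations * len(self.snr_levels_db)

    @property
    def n_rows(self) -> int:
        """Metric rows: grid size times methods (filters + no-filter)."""
        return self.grid_size * (len(self.filters) + 1)


def _realization_seed(master_seed: int, setup: int, lead: int, realization: int) -> int:
    """Counter-style per-cell seed (documented scheme: spawn key (1, s, l, r))."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(1, setup, lead, realization))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_grid(config: ExperimentConfig, records=None, filter_subset_mask=None) -> pd.DataFrame:
    """Run the full generate -> corrupt -> filter -> score grid.

    Parameters
    ----------
    config : ExperimentConfig
    records : iterable of EcgRecord, optional
        Pre-generated clean records; defaults to the synthetic setup grid
        derived from ``config``.
    filter_subset_mask : callable, optional
        ``mask(setup_index, realization_index) -> bool``; when given, the
        filtering methods run only on cells where it returns True (the
        no-filter condition always runs).  Used to score filters on a
        balanced subset of a larger corruption grid.

    Returns
    -------
    pandas.DataFrame with :data:`METRIC_COLUMNS`.  Filter failures are
    recorded as flagged rows (``status`` column), never raised.
    """
    if records is None:
        records = generate_setup_grid(config.n_setups, config.master_seed,
                                      duration=config.duration)
    rows: list[tuple] = []
    for i_setup, record in enumerate(records):
        spec = BaselineSpec(fs=record.fs, n_samples=record.n_samples)
        kp = locate_kp(record)
        margin_samples = round(config.trim_margin * record.fs)
        anchors = record.spline_anchors()
        record_id = record.meta.get("record_id", f"setup-{i_setup:04d}")
        for lead in range(record.n_leads):
            x = record.leads[lead]
            x_t = trim_boundaries(x, record.fs, config.trim_margin)
            for i_real in range(config.n_realizations):
                seed = _realization_seed(config.master_seed, i_setup, lead, i_real)
                b_unit = render(draw_realization(spec, seed), spec)
                run_filters = (filter_subset_mask is None
                               or filter_subset_mask(i_setup, i_real))
                for snr_db in config.snr_levels_db:
                    b, _ = scale_to_snr(b_unit, x, snr_db)
                    y = corrupt(x, b)
                    methods = ["none"] + (list(config.filters) if run_filters else [])
                    for method in methods:
                        if method == "none":
                            out = FilterOutput(x_hat=y, elapsed=0.0, method="none")
                            status = "ok"
                        else:
                            try:
                                out = apply_filter(method, y, record.fs, anchors=anchors)
                                status = "ok"
                            except Exception as exc:  # flagged row, not a crash
                                logger.warning("filter %s failed on %s lead %d: %s",
                                               method, record_id, lead, exc)
                                rows.append((record_id, lead, i_real, snr_db, method,
                                             np.nan, np.nan, np.nan, np.nan,
                                             f"error: {exc}"))
                                continue
                        xh_t = trim_boundaries(out.x_hat, record.fs, config.trim_margin)
                        cc = correlation_coefficient(x_t, xh_t)
                        l_op = l_operator(x_t, xh_t)
                        dkp = kp_deviation(x, out.x_hat, kp, margin_samples=margin_samples)
                        rows.append((record_id, lead, i_real, snr_db, method,
                                     cc, l_op, dkp, out.elapsed, status))
        logger.info("setup %s scored (%d rows so far)", record_id, len(rows))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def _iqr(values: np.ndarray) -> float:
    """Q3 - Q1 with linear interpolation between order statistics."""
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


@dataclass
class SummaryTable:
    """Per-method MED/IQR of each criterion plus per-criterion winners."""

    table: pd.DataFrame
    winners: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [self.table.to_string(float_format=lambda v: f"{v:.4f}")]
        for crit, w in self.winners.items():
            flag = "clear winner" if w["significant"] else "no clear winner"
            lines.append(f"{crit}: best median = {w['candidates'][0]} "
                         f"(max pairwise p = {w['max_p']:.3g}; {flag})")
        return "\n".join(lines)


def summarize(rows: pd.DataFrame, alpha: float = 0.05,
              alternative: str = "greater") -> SummaryTable:
    """MED +/- IQR per (method, criterion) and the winner of each criterion."""
    if rows.empty:
        raise ContractError("empty metric table")
    ok = rows[rows["status"] == "ok"]
    dropped = len(rows) - len(ok)
    if dropped:
        logger.warning("excluding %d flagged rows from the summary", dropped)
    out = {}
    for method, grp in ok.groupby("filter"):
        entry = {}
        for crit, spec in CRITERIA.items():
            vals = grp[spec["column"]].to_numpy()
            entry[f"{crit}_med"] = float(np.median(vals))
            entry[f"{crit}_iqr"] = _iqr(vals)
        out[method] = entry
    table = pd.DataFrame(out).T
    winners = {}
    for crit in CRITERIA:
        try:
            winners[crit] = determine_winner(ok, crit, alpha=alpha,
                                             alternative=alternative)
        except ContractError:
            pass  # fewer than two methods present
    return SummaryTable(table=table, winners=winners)


def wilcoxon_signed_rank(a, b, alternative: str = "greater") -> float:
    """Paired Wilcoxon signed-rank p-value that ``a`` exceeds ``b``.

    Zero differences are dropped; if all differences are zero the test carries
    no evidence and p = 1 is returned.  Small samples (n <= 25 after zero
    removal) use the exact sign-flip null distribution (average ranks for
    tied magnitudes), larger ones the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    if d.size <= 25:
        return _exact_signflip_p(d, alternative)
    res = stats.wilcoxon(d, alternative=alternative, method="approx")
    return float(res.pvalue)


def _exact_signflip_p(d: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by enumerating the 2^n sign assignments via DP.

    Average ranks are doubled to integers so tied magnitudes are handled
    exactly; the null distribution of W+ is built by dynamic programming.
    """
    ranks2 = np.rint(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else 2 * counts
    counts /= counts.sum()
    p_greater = counts[w_obs:].sum()
    p_less = counts[: w_obs + 1].sum()
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2.0 * min(p_greater, p_less)))


_PAIR_KEYS = ["record_id", "lead", "realization", "snr_db"]


def _paired_values(ok: pd.DataFrame, column: str, method_a: str, method_b: str,
                   absolute: bool) -> tuple[np.ndarray, np.ndarray]:
    sub = ok[ok["filter"].isin([method_a, method_b])]
    wide = sub.pivot_table(index=_PAIR_KEYS, columns="filter", values=column,
                           aggfunc="first").dropna()
    va = wide[method_a].to_numpy()
    vb = wide[method_b].to_numpy()
    if absolute:
        va, vb = np.abs(va), np.abs(vb)
    return va, vb


def determine_winner(rows: pd.DataFrame, criterion: str, alpha: float = 0.05,
                     alternative: str = "greater") -> dict:
    """Best-median method and the worst (maximum) pairwise p-value.

    For cc/l_op the best median is the highest and pairs are tested one-sided
    for being greater; for dkp the smallest |median| (IQR tie-break) is best
    and |deviations| are tested for being smaller; for elapsed the lowest
    median wins.  A tie in medians yields all tied candidates and no winner.
    """
    if criterion not in CRITERIA:
        raise InvalidParameterError(f"unknown criterion {criterion!r}")
    spec = CRITERIA[criterion]
    ok = rows[rows["status"] == "ok"]
    methods = sorted(ok["filter"].unique())
    if criterion == "elapsed":
        # the no-filter condition spends no time; it is not a timing comparator
        methods = [m for m in methods if m != "none"]
    if len(methods) < 2:
        raise ContractError("winner rule needs at least two methods")
    filters_only = [m for m in methods if m != "none"]

    med = {}
    iqr = {}
    for m in methods:
        vals = ok.loc[ok["filter"] == m, spec["column"]].to_numpy()
        v = np.abs(np.median(vals)) if spec["absolute"] else np.median(vals)
        med[m] = float(v)
        iqr[m] = _iqr(vals)
    # candidates come from the filtering techniques; no-filter only compares
    best_pool = {m: med[m] for m in filters_only}
    best = max(best_pool.values()) if spec["higher_is_better"] else min(best_pool.values())
    candidates = [m for m in filters_only if med[m] == best]
    if len(candidates) > 1:
        # break dkp ties by IQR per the robustness argument; others stay tied
        if spec["absolute"]:
            best_iqr = min(iqr[m] for m in candidates)
            candidates = [m for m in candidates if iqr[m] == best_iqr]
    if len(candidates) > 1:
        return {"criterion": criterion, "candidates": candidates, "max_p": np.nan,
                "significant": False, "medians": med}

    cand = candidates[0]
    if alternative == "two-sided":
        alt = "two-sided"
    else:
        alt = "greater" if spec["higher_is_better"] else "less"
    p_values = {}
    for other in methods:
        if other == cand:
            continue
        va, vb = _paired_values(ok, spec["column"], cand, other,
                                absolute=spec["absolute"])
        p_values[other] = wilcoxon_signed_rank(va, vb, alternative=alt)
    max_p = max(p_values.values())
    return {
        "criterion": criterion,
        "candidates": candidates,
        "p_values": p_values,
        "max_p": float(max_p),
        "significant": bool(max_p < alpha),
        "medians": med,
    }
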
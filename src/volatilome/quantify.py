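"""Semi-quantification, Kovats retention indices and technical-replicate QC.

GC-MS peak areas are converted to internal-standard equivalents
(ug per 100 g of dried fruit powder):

    m_i = (K_i / K_IS) * (A_i / A_IS) * (m_IS / m_p) * 100

with the response-factor ratio K_i/K_IS fixed at 1, A the peak areas of the
analyte and the spiked internal standard, m_IS the standard quantity and
m_p the powder quantity. The two-stage replicate QC then removes low-quality
runs before the three technical replicates are averaged into the
samples x volatiles phenotype matrix:

1. Per (sample, volatile) triplet with CV > 50%: if exactly one of the
   extreme replicates deviates from the median by more than 55% while the
   other deviates by less than 35%, that single deviant is excluded.
2. Triplets left unresolved by rule 1 are arbitrated per sample: if one run
   index is the farthest-from-median replicate in a strict majority of the
   sample's high-CV volatiles, that run is excluded for the unresolved ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlkaneLadder",
    "QcDecision",
    "semi_quantify",
    "kovats_ri",
    "qc_filter_triplet",
    "qc_run_arbitration",
    "apply_qc",
    "assemble_matrix",
    "decisions_frame",
]

CV_THRESHOLD = 50.0
DEVIATION_LOW = 35.0
DEVIATION_HIGH = 55.0

REASON_CV_OK = "cv_ok"
REASON_SINGLE_DEVIANT = "single_deviant_excluded"
REASON_ARBITRATION = "run_arbitration_excluded"
REASON_UNRESOLVED = "unresolved"


def semi_quantify(area, area_istd, mass_istd, mass_powder, response_ratio=1.0):
    """Concentration in internal-standard equivalents (ug/100 g).

    Linear in ``area`` and ``mass_istd``, inverse-linear in ``area_istd``
    and ``mass_powder``. Accepts scalars or arrays; missing areas (NaN)
    propagate.
    """
    area = np.asarray(area, dtype=float)
    area_istd = np.asarray(area_istd, dtype=float)
    mass_istd = np.asarray(mass_istd, dtype=float)
    mass_powder = np.asarray(mass_powder, dtype=float)
    if np.any(area_istd <= 0):
        raise ValueError("internal-standard peak area must be positive")
    if np.any(mass_powder <= 0):
        raise ValueError("powder quantity must be positive")
    if np.any(area[~np.isnan(area)] < 0):
        raise ValueError("negative peak area")
    out = response_ratio * (area / area_istd) * (mass_istd / mass_powder) * 100.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AlkaneLadder:
    """Co-injected n-alkane series (carbon number, retention time in min)."""

    carbons: tuple[int, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.times) or len(self.carbons) < 2:
            raise ValueError("ladder needs >= 2 (carbon, time) points")
        if np.any(np.diff(self.carbons) <= 0):
            raise ValueError("carbon numbers must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("retention times must be strictly increasing")

    @classmethod
    def c8_to_c20(cls, times) -> "AlkaneLadder":
        return cls(carbons=tuple(range(8, 21)), times=tuple(float(t) for t in times))


def kovats_ri(t_x: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index by the linear (temperature-programmed)
    convention: 100*n + 100*(t_x - t_n)/(t_{n+1} - t_n) between the
    bracketing alkanes. No extrapolation outside the ladder.
    """
    times = np.asarray(ladder.times)
    carbons = np.asarray(ladder.carbons)
    if not times[0] <= t_x <= times[-1]:
        raise ValueError(
            f"retention time {t_x} outside alkane ladder range [{times[0]}, {times[-1]}]"
        )
    k = int(np.searchsorted(times, t_x, side="right")) - 1
    k = min(k, len(times) - 2)
    frac = (t_x - times[k]) / (times[k + 1] - times[k])
    return 100.0 * carbons[k] + 100.0 * frac * (carbons[k + 1] - carbons[k])


@dataclass(frozen=True)
class QcDecision:
    """Keep/exclude outcome for one (sample, volatile) replicate set."""

    sample: str
    volatile: str
    kept: tuple[int, ...]
    excluded: tuple[int, ...]
    reason: str

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.excluded):
            raise ValueError("a run cannot be both kept and excluded")


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return 0.0
    return float(values.std(ddof=1) / mean * 100.0)


def qc_filter_triplet(values, sample: str = "", volatile: str = "") -> QcDecision:
    """First-stage QC decision for one replicate set.

    ``values`` maps run index -> concentration (or is a sequence indexed by
    run 1..n, NaN = missing). With fewer than 3 non-missing replicates, or
    CV <= 50%, everything is kept. Otherwise the min and max replicates'
    deviations from the median, |x - median| / median, are examined: exactly
    one deviation > 55% with the other < 35% excludes the larger-deviation
    replicate; anything else is left unresolved for run arbitration. The
    decision depends only on the multiset of values, not their order.
    """
    if isinstance(values, dict):
        items = sorted(values.items())
    else:
        items = list(enumerate(np.asarray(values, dtype=float), start=1))
    runs = np.array([r for r, v in items])
    vals = np.array([float(v) for r, v in items])
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError(f"all replicates missing for ({sample}, {volatile})")
    runs, vals = runs[ok], vals[ok]
    all_runs = tuple(int(r) for r in runs)

    if len(vals) < 3 or _cv_percent(vals) <= CV_THRESHOLD:
        return QcDecision(sample, volatile, all_runs, (), REASON_CV_OK)

    order = np.argsort(vals, kind="stable")
    median = float(vals[order[len(vals) // 2]])
    if median == 0:
        return QcDecision(sample, volatile, all_runs, (), REASON_UNRESOLVED)
    i_min, i_max = order[0], order[-1]
    dev = np.abs(vals - median) / median * 100.0
    dev_min, dev_max = dev[i_min], dev[i_max]
    lo, hi = sorted((dev_min, dev_max))
    if hi > DEVIATION_HIGH and lo < DEVIATION_LOW:
        deviant = i_max if dev_max >= dev_min else i_min
        kept = tuple(int(r) for r in runs[np.arange(len(runs)) != deviant])
        return QcDecision(sample, volatile, kept, (int(runs[deviant]),), REASON_SINGLE_DEVIANT)
    return QcDecision(sample, volatile, all_runs, (), REASON_UNRESOLVED)


def _implicated_run(vals: np.ndarray, runs: np.ndarray) -> int:
    """Run index of the replicate farthest from the triplet median."""
    order = np.argsort(vals, kind="stable")
    median = vals[order[len(vals) // 2]]
    return int(runs[np.argmax(np.abs(vals - median))])


def qc_run_arbitration(
    concentrations: pd.DataFrame, decisions: list[QcDecision]
) -> list[QcDecision]:
    """Second-stage QC: per-sample arbitration of unresolved triplets.

    ``concentrations`` is the tidy semi-quantified replicate table (columns
    sample, volatile, run, value). For each sample with unresolved
    decisions, the run implicated (farthest from the median) is tallied over
    all of that sample's high-CV volatiles (those not decided ``cv_ok``); a
    strict majority for one run excludes it from the unresolved volatiles.
    Without a strict majority all three replicates are retained.
    """
    unresolved_by_sample: dict[str, list[int]] = {}
    highcv_by_sample: dict[str, list[int]] = {}
    for i, d in enumerate(decisions):
        if d.reason == REASON_UNRESOLVED:
            unresolved_by_sample.setdefault(d.sample, []).append(i)
        if d.reason in (REASON_UNRESOLVED, REASON_SINGLE_DEVIANT):
            highcv_by_sample.setdefault(d.sample, []).append(i)
    if not unresolved_by_sample:
        return decisions

    out = list(decisions)
    grouped = {
        key: grp for key, grp in concentrations.groupby(["sample", "volatile"], sort=False)
    }
    for sample, unresolved_idx in unresolved_by_sample.items():
        votes: dict[int, int] = {}
        n_votes = 0
        for i in highcv_by_sample[sample]:
            d = decisions[i]
            grp = grouped[(sample, d.volatile)].dropna(subset=["value"])
            if len(grp) < 3:
                continue
            run = _implicated_run(grp["value"].to_numpy(), grp["run"].to_numpy())
            votes[run] = votes.get(run, 0) + 1
            n_votes += 1
        if not votes:
            continue
        top_run, top_count = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        if top_count * 2 <= n_votes:  # strict majority required
            continue
        for i in unresolved_idx:
            d = decisions[i]
            if top_run in d.kept:
                kept = tuple(r for r in d.kept if r != top_run)
                out[i] = QcDecision(d.sample, d.volatile, kept, (top_run,), REASON_ARBITRATION)
    return out


def _tidy_concentrations(replicates: pd.DataFrame) -> pd.DataFrame:
    """Semi-quantify a tidy replicate table into (sample, volatile, run, value)."""
    required = {"sample", "volatile", "run", "area", "area_istd", "mass_istd", "mass_powder"}
    missing_cols = required - set(replicates.columns)
    if missing_cols:
        raise ValueError(f"replicate table missing columns: {sorted(missing_cols)}")
    value = semi_quantify(
        replicates["area"].to_numpy(),
        replicates["area_istd"].to_numpy(),
        replicates["mass_istd"].to_numpy(),
        replicates["mass_powder"].to_numpy(),
    )
    return pd.DataFrame(
        {
            "sample": replicates["sample"].to_numpy(),
            "volatile": replicates["volatile"].to_numpy(),
            "run": replicates["run"].to_numpy(),
            "value": value,
        }
    )


def apply_qc(replicates: pd.DataFrame) -> tuple[pd.DataFrame, list[QcDecision]]:
    """Run semi-quantification and both QC stages over a replicate table.

    Returns the tidy concentration table and the final decision list (one
    decision per (sample, volatile) with at least one non-missing run; fully
    missing cells carry no decision and assemble as missing).
    """
    conc = _tidy_concentrations(replicates)
    wide = conc.pivot_table(
        index=["sample", "volatile"], columns="run", values="value", sort=False
    )
    run_cols = sorted(wide.columns)
    arr = wide[run_cols].to_numpy()
    n_ok = (~np.isnan(arr)).sum(axis=1)

    # vectorised fast path: full triplets whose CV is already acceptable
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=1)
        sds = np.nanstd(arr, axis=1, ddof=1)
        cv = np.where(means != 0, sds / np.abs(means) * 100.0, 0.0)
    full = n_ok == len(run_cols)
    easy = (n_ok > 0) & (~full | (cv <= CV_THRESHOLD))

    decisions: list[QcDecision] = []
    keys = wide.index.to_list()
    for i, (sample, volatile) in enumerate(keys):
        if n_ok[i] == 0:
            continue
        if easy[i]:
            kept = tuple(int(run_cols[j]) for j in np.flatnonzero(~np.isnan(arr[i])))
            decisions.append(QcDecision(sample, volatile, kept, (), REASON_CV_OK))
        else:
            vals = {int(r): arr[i, j] for j, r in enumerate(run_cols)}
            decisions.append(qc_filter_triplet(vals, sample, volatile))
    decisions = qc_run_arbitration(conc, decisions)
    return conc, decisions


def assemble_matrix(
    replicates: pd.DataFrame, decisions: list[QcDecision] | None = None
) -> tuple[pd.DataFrame, float]:
    """Average kept replicates into the samples x volatiles phenotype matrix.

    When ``decisions`` is None the full QC chain is applied first. Returns
    the matrix (NaN = missing) and the missing-cell fraction computed from
    the actual grid dimensions.
    """
    conc = _tidy_concentrations(replicates)
    if decisions is None:
        _, decisions = apply_qc(replicates)
    samples = list(dict.fromkeys(conc["sample"]))
    volatiles = list(dict.fromkeys(conc["volatile"]))
    lookup = {
        (s, v, int(r)): val
        for s, v, r, val in zip(conc["sample"], conc["volatile"], conc["run"], conc["value"])
    }
    matrix = pd.DataFrame(np.nan, index=samples, columns=volatiles)
    for d in decisions:
        if not d.kept:
            continue
        vals = [lookup[(d.sample, d.volatile, r)] for r in d.kept]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            matrix.loc[d.sample, d.volatile] = float(np.mean(vals))
    matrix.index.name = "sample"
    missing_fraction = float(matrix.isna().to_numpy().mean())
    return matrix, missing_fraction


def decisions_frame(decisions: list[QcDecision]) -> pd.DataFrame:
    """QC audit table: one row per decision."""
    return pd.DataFrame(
        {
            "sample": [d.sample for d in decisions],
            "volatile": [d.volatile for d in decisions],
            "kept_runs": [",".join(map(str, d.kept)) for d in decisions],
            "excluded_runs": [",".join(map(str, d.excluded)) for d in decisions],
            "reason": [d.reason for d in decisions],
        }
    )
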
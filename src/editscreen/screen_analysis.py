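"""Screening statistics for the dual-luciferase editing reporter.

The per-well readout is the Nluc/FFL luminescence ratio. Each plate is
normalised to its own controls — the negative (vehicle) control mean maps
to 0% inhibition and the positive (Nluc-inhibitor) control mean to 100% —
so plates and runs are comparable. Plate quality is gated on the Z'-factor

    Z' = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

computed on the ratio channel from the control wells (sample means and
SDs). Hit calling applies a cytotoxicity filter first: compounds whose FFL
signal drops more than 40% below the negative-control mean are removed as
likely toxic or unspecific translational inhibitors, whatever their ratio
says. Surviving compounds are hits at >= 70% ratio inhibition, activators
at or below a (configurable) negative threshold. Confirmed hits are
retested at several concentrations and judged on monotone dose response;
IC50s come from a four-parameter logistic fit.

Thresholds are fixed percentages, not p-values; no multiple-testing
correction is applied anywhere, deliberately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .plate_model import Plate, Role, Well

logger = logging.getLogger(__name__)

HIT_THRESHOLD = 70.0  # % ratio inhibition, inclusive
TOX_THRESHOLD = 40.0  # % FFL inhibition, strict
ACTIVATOR_THRESHOLD = -50.0  # % ratio inhibition, inclusive (i.e. >=50% activation)
ZPRIME_MIN = 0.4

RESULT_COLUMNS = [
    "compound_id",
    "plate_id",
    "well",
    "ratio",
    "pct_inhibition",
    "pct_ffl_inhibition",
    "toxic_flag",
    "hit_flag",
    "activator_flag",
]


@dataclass(frozen=True)
class PlateQC:
    """Per-plate control summaries and the Z'-factor gate."""

    plate_id: str
    mu_n: float
    sigma_n: float
    mu_p: float
    sigma_p: float
    mu_n_ffl: float
    zprime: float
    passed: bool
    n_neg: int = 0
    n_pos: int = 0
    error: str | None = None


@dataclass(frozen=True)
class ExcludedWell:
    plate_id: str
    well: str
    compound_id: str | None
    reason: str


@dataclass
class ScreenResult:
    """Output of :func:`call_hits`: per-compound calls plus QC and exclusions."""

    results: pd.DataFrame
    plate_qc: list[PlateQC]
    excluded_wells: list[ExcludedWell] = field(default_factory=list)
    excluded_plates: list[str] = field(default_factory=list)

    @property
    def hits(self) -> list[str]:
        r = self.results
        return sorted(r.loc[r["hit_flag"], "compound_id"])

    @property
    def activators(self) -> list[str]:
        r = self.results
        return sorted(r.loc[r["activator_flag"], "compound_id"])

    @property
    def toxic(self) -> list[str]:
        r = self.results
        return sorted(r.loc[r["toxic_flag"], "compound_id"])

    def qc_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(q) for q in self.plate_qc])

    def summary(self) -> dict:
        n_screened = int(len(self.results))
        n_hits = len(self.hits)
        return {
            "n_plates": len(self.plate_qc),
            "n_plates_failed_qc": len(self.excluded_plates),
            "n_compounds_screened": n_screened,
            "n_hits": n_hits,
            "n_activators": len(self.activators),
            "n_toxic_filtered": len(self.toxic),
            "n_wells_excluded": len(self.excluded_wells),
            "hit_rate_pct": hit_rate(n_hits, n_screened) if n_screened else None,
            "mean_zprime": float(np.mean([q.zprime for q in self.plate_qc if math.isfinite(q.zprime)]))
            if self.plate_qc
            else None,
        }


def well_ratio(nluc: float, ffl: float) -> float:
    """Nluc/FFL — the editing readout of one well. Requires FFL > 0.

    A non-positive FFL denominator means a dead or empty well; callers
    catch the ``ValueError`` and record an exclusion rather than scoring 0.
    """
    if ffl is None or nluc is None or not ffl > 0:
        raise ValueError(f"cannot form Nluc/FFL ratio with FFL={ffl!r} (dead well?)")
    return nluc / ffl


def zprime(neg: Sequence[float], pos: Sequence[float]) -> float:
    """Screening-window Z'-factor from control ratio values.

    ``1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|`` with sample SDs
    (ddof=1). 1.0 is a perfect separation; values >= ~0.4 are usable.
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need at least 2 control values per group")
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        raise ValueError("control means are equal; Z' is undefined")
    sigma_n, sigma_p = neg.std(ddof=1), pos.std(ddof=1)
    return 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)


def pct_inhibition(value: float, mu_n: float, mu_p: float) -> float:
    """Percent inhibition: neg-control mean -> 0%, pos-control mean -> 100%.

    Values beyond the positive control exceed 100; values above the
    negative control are negative (activation).
    """
    if mu_n == mu_p:
        raise ValueError("control means are equal; normalization is undefined")
    return 100.0 * (mu_n - value) / (mu_n - mu_p)


def ffl_inhibition(ffl: float, mu_n_ffl: float) -> float:
    """Percent FFL loss vs the negative-control FFL mean (toxicity channel).

    Only the negative control anchors this scale: the Nluc-inhibitor
    positive control does not alter FFL.
    """
    if not mu_n_ffl > 0:
        raise ValueError("negative-control FFL mean must be > 0")
    return 100.0 * (1.0 - ffl / mu_n_ffl)


def _control_ratios(plate: Plate, role: Role) -> tuple[list[float], list[ExcludedWell]]:
    values, excluded = [], []
    for w in plate.wells_with_role(role):
        try:
            values.append(well_ratio(w.nluc, w.ffl))
        except ValueError as exc:
            excluded.append(ExcludedWell(plate.plate_id, str(w.address), None, str(exc)))
    return values, excluded


def qc_plate(plate: Plate, z_min: float = ZPRIME_MIN) -> PlateQC:
    """Control summaries and Z' for one plate; ``passed`` gates on ``z_min``."""
    neg, excl_n = _control_ratios(plate, Role.NEG_CONTROL)
    pos, excl_p = _control_ratios(plate, Role.POS_CONTROL)
    for e in excl_n + excl_p:
        logger.warning("plate %s: control well %s excluded (%s)", e.plate_id, e.well, e.reason)
    neg_ffl = [w.ffl for w in plate.wells_with_role(Role.NEG_CONTROL) if w.ffl and w.ffl > 0]
    mu_n_ffl = float(np.mean(neg_ffl)) if neg_ffl else float("nan")
    try:
        if len(neg) < 2 or len(pos) < 2:
            raise ValueError("fewer than 2 valid control ratios in a group")
        z = zprime(neg, pos)
        return PlateQC(
            plate.plate_id,
            mu_n=float(np.mean(neg)),
            sigma_n=float(np.std(neg, ddof=1)),
            mu_p=float(np.mean(pos)),
            sigma_p=float(np.std(pos, ddof=1)),
            mu_n_ffl=mu_n_ffl,
            zprime=z,
            passed=z >= z_min,
            n_neg=len(neg),
            n_pos=len(pos),
        )
    except ValueError as exc:
        logger.warning("plate %s fails QC: %s", plate.plate_id, exc)
        return PlateQC(
            plate.plate_id,
            mu_n=float(np.mean(neg)) if neg else float("nan"),
            sigma_n=float("nan"),
            mu_p=float(np.mean(pos)) if pos else float("nan"),
            sigma_p=float("nan"),
            mu_n_ffl=mu_n_ffl,
            zprime=float("nan"),
            passed=False,
            n_neg=len(neg),
            n_pos=len(pos),
            error=str(exc),
        )


def call_hits(
    plates: Iterable[Plate],
    hit_threshold: float = HIT_THRESHOLD,
    tox_threshold: float = TOX_THRESHOLD,
    activator_threshold: float = ACTIVATOR_THRESHOLD,
    z_min: float = ZPRIME_MIN,
) -> ScreenResult:
    """Normalise every compound well to its plate's controls and call hits.

    Per compound: ratio inhibition from the plate's control means; toxic
    if FFL inhibition exceeds ``tox_threshold`` (strict, per "higher
    than"); a hit if non-toxic and ratio inhibition >= ``hit_threshold``
    (inclusive, per "threshold set to"); an activator if non-toxic and
    ratio inhibition at or below ``activator_threshold``. Plates failing
    the Z' gate are excluded whole, with a log entry. A compound present
    on more than one plate is an error: the single-concentration screen
    has no replicate-merging policy.
    """
    results: list[dict] = []
    qcs: list[PlateQC] = []
    excluded_wells: list[ExcludedWell] = []
    excluded_plates: list[str] = []
    seen: dict[str, str] = {}

    for plate in sorted(plates, key=lambda p: p.plate_id):
        qc = qc_plate(plate, z_min=z_min)
        qcs.append(qc)
        if not qc.passed:
            logger.warning("plate %s excluded from hit calling (Z'=%s)", plate.plate_id, qc.zprime)
            excluded_plates.append(plate.plate_id)
            continue
        for w in plate.wells_with_role(Role.COMPOUND):
            if w.compound_id in seen:
                raise ValueError(
                    f"compound {w.compound_id} appears on plates "
                    f"{seen[w.compound_id]} and {plate.plate_id}; "
                    "replicates are not supported in a primary screen"
                )
            seen[w.compound_id] = plate.plate_id
            try:
                ratio = well_ratio(w.nluc, w.ffl)
            except ValueError as exc:
                excluded_wells.append(
                    ExcludedWell(plate.plate_id, str(w.address), w.compound_id, str(exc))
                )
                continue
            inhib = pct_inhibition(ratio, qc.mu_n, qc.mu_p)
            ffl_inhib = ffl_inhibition(w.ffl, qc.mu_n_ffl)
            toxic = ffl_inhib > tox_threshold
            results.append(
                {
                    "compound_id": w.compound_id,
                    "plate_id": plate.plate_id,
                    "well": str(w.address),
                    "ratio": ratio,
                    "pct_inhibition": inhib,
                    "pct_ffl_inhibition": ffl_inhib,
                    "toxic_flag": toxic,
                    "hit_flag": (not toxic) and inhib >= hit_threshold,
                    "activator_flag": (not toxic) and inhib <= activator_threshold,
                }
            )
    for e in excluded_wells:
        logger.warning(
            "well %s/%s (compound %s) excluded: %s", e.plate_id, e.well, e.compound_id, e.reason
        )
    frame = pd.DataFrame(results, columns=RESULT_COLUMNS)
    frame = frame.sort_values("compound_id", kind="stable").reset_index(drop=True)
    return ScreenResult(frame, qcs, excluded_wells, excluded_plates)


def hit_rate(n_active: int, n_screened: int) -> float:
    """Primary hit rate in percent, reported to one decimal (300/33000 -> 0.9)."""
    if n_screened <= 0:
        raise ValueError("n_screened must be > 0")
    if not 0 <= n_active <= n_screened:
        raise ValueError("need 0 <= n_active <= n_screened")
    return round(100.0 * n_active / n_screened, 1)


# ---------------------------------------------------------------------------
# Dose-response


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of percent inhibition vs dose."""

    doses: tuple[float, ...]
    responses: tuple[float, ...]
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool


def _4pl(dose: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ic50 - np.log(dose))))


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    constrained: bool = False,
) -> DoseResponseFit:
    """Least-squares 4PL fit; IC50 is fit on the log scale.

    ``constrained=True`` fixes bottom/top at 0/100 (the 2-parameter
    variant used for sparse 3-point confirmation data). Non-convergence —
    optimizer failure, a flat response, or an IC50 more than two decades
    outside the tested dose range — is reported through ``converged``,
    never an exception.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.size != r.size or d.size < (3 if constrained else 4):
        raise ValueError("need matched dose/response arrays (>=4 points, 3 if constrained)")
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")

    def failed() -> DoseResponseFit:
        return DoseResponseFit(tuple(d), tuple(r), float("nan"), float("nan"),
                               float("nan"), float("nan"), converged=False)

    if np.ptp(r) < 1e-9:
        return failed()
    log_mid = float(np.log(np.sqrt(d.min() * d.max())))
    try:
        if constrained:
            popt, _ = optimize.curve_fit(
                lambda x, log_ic50, hill: _4pl(x, 0.0, 100.0, log_ic50, hill),
                d, r, p0=[log_mid, 1.0], maxfev=10000,
            )
            bottom, top, log_ic50, hill = 0.0, 100.0, popt[0], popt[1]
        else:
            popt, _ = optimize.curve_fit(
                _4pl, d, r,
                p0=[float(r.min()), float(r.max()), log_mid, 1.0],
                maxfev=10000,
            )
            bottom, top, log_ic50, hill = popt
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return failed()
    ic50 = float(np.exp(log_ic50))
    in_range = d.min() * 1e-2 <= ic50 <= d.max() * 1e2
    return DoseResponseFit(
        tuple(d), tuple(r), ic50, float(hill), float(top), float(bottom),
        converged=bool(in_range and np.isfinite(ic50)),
    )


# ---------------------------------------------------------------------------
# Retest / confirmation

RETEST_DOSES = (2.5, 5.0, 10.0)
MONOTONE_TOLERANCE = 10.0  # points of inhibition a dose step may dip


def retest(
    hit_ids: Sequence[str],
    dose_tables: Mapping[float, Iterable[Plate]],
    hit_threshold: float = HIT_THRESHOLD,
    mono_tol: float = MONOTONE_TOLERANCE,
    z_min: float = ZPRIME_MIN,
) -> pd.DataFrame:
    """Confirm primary hits against independent multi-dose measurements.

    ``dose_tables`` maps each tested concentration to plates (with
    controls) carrying the retested compounds. A hit is ``confirmed`` when
    every dose was measurable, inhibition is monotone non-decreasing with
    dose up to a ``mono_tol``-point noise allowance, and the top dose
    reaches ``hit_threshold``. Hits missing any dose are ``untestable``.
    """
    doses = sorted(dose_tables)
    per_dose: dict[float, pd.DataFrame] = {}
    for dose in doses:
        res = call_hits(
            dose_tables[dose],
            hit_threshold=hit_threshold,
            tox_threshold=float("inf"),  # toxicity already filtered upstream
            z_min=z_min,
        )
        per_dose[dose] = res.results.set_index("compound_id")

    rows = []
    for cid in hit_ids:
        inhibs: dict[str, float] = {}
        missing = False
        for dose in doses:
            table = per_dose[dose]
            if cid in table.index:
                inhibs[f"inhib_{dose:g}"] = float(table.loc[cid, "pct_inhibition"])
            else:
                inhibs[f"inhib_{dose:g}"] = float("nan")
                missing = True
        series = [inhibs[f"inhib_{d:g}"] for d in doses]
        monotone = all(b >= a - mono_tol for a, b in zip(series, series[1:]))
        confirmed = (not missing) and monotone and series[-1] >= hit_threshold
        rows.append(
            {
                "compound_id": cid,
                **inhibs,
                "untestable": missing,
                "confirmed": confirmed,
            }
        )
    return pd.DataFrame(rows)
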
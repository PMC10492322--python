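"""Targeted MRM quantitation: IS normalization, weighted calibration, QC gates.

Integrated peak areas become absolute concentrations in four steps:

1. each quantifier area is divided by its stable-isotope internal-standard
   (IS) area, cancelling matrix suppression and injection-volume drift;
2. the calibrator response ratios are regressed on nominal concentration by
   weighted least squares (weighting 1/x by default), and the curve is
   accepted only when the weighted r-squared exceeds 0.99;
3. unknowns are back-calculated through the accepted curve, flagging values
   outside the calibrated range (below LLOQ / above ULOQ, limits inclusive);
4. batch-level QC: pooled-serum imprecision (CV) and inaccuracy (bias) must
   both stay below 15%, and each sample's quantifier/qualifier ion ratio must
   sit within 15% of the reference mean (analytes without a qualifier
   transition, such as SDMA and ADMA, are exempt).

Default analyte/IS pairing follows the arginine assay: arginine against
13C6-arginine, SDMA and ADMA against D7-ADMA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MrmAssayConfig",
    "CalibrationCurve",
    "default_assay_configs",
    "is_normalize",
    "fit_calibration",
    "back_calculate",
    "ion_ratio_qc",
    "batch_accept",
    "quantify_batch",
]

FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_ION_RATIO = "ion_ratio_fail"
FLAG_NO_IS = "no_is"
FLAG_BATCH = "batch_failed"


@dataclass
class MrmAssayConfig:
    """Per-analyte assay acceptance settings.

    ``weighting`` is one of ``none``, ``1/x``, ``1/x^2``; ``lloq`` must equal
    the lowest calibrator level and the top level is the ULOQ.
    ``masked_levels`` lists calibrator nominal concentrations excluded from
    the fit after manual inspection.  ``pooled_nominal`` is the
    previously-characterized pooled-serum concentration used for the bias
    gate; when absent the bias gate is skipped with a warning.
    """

    name: str
    is_name: str
    calibrator_levels: list[float]
    has_qualifier: bool = True
    weighting: str = "1/x"
    r2_min: float = 0.99
    ion_ratio_tolerance: float = 0.15
    qc_cv_max: float = 0.15
    qc_bias_max: float = 0.15
    masked_levels: list[float] = field(default_factory=list)
    pooled_nominal: float | None = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.calibrator_levels, dtype=float)
        if lv.size < 2 or not np.all(np.diff(lv) > 0):
            raise ValueError(f"{self.name}: calibrator levels must increase")
        if self.weighting not in ("none", "1/x", "1/x^2"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        for tol in (self.ion_ratio_tolerance, self.qc_cv_max, self.qc_bias_max):
            if not 0 < tol < 1:
                raise ValueError("tolerances must lie in (0, 1)")

    @property
    def lloq(self) -> float:
        return float(self.calibrator_levels[0])

    @property
    def uloq(self) -> float:
        return float(self.calibrator_levels[-1])


def default_assay_configs() -> dict[str, MrmAssayConfig]:
    """The arginine / SDMA / ADMA serum assay with its published settings."""
    return {
        "ARG": MrmAssayConfig(
            "ARG", "13C6-ARG", [4.0, 8.0, 20.0, 40.0, 100.0, 200.0],
            has_qualifier=True,
        ),
        "SDMA": MrmAssayConfig(
            "SDMA", "D7-ADMA", [0.2, 0.4, 1.0, 2.0, 5.0, 10.0],
            has_qualifier=False,
        ),
        "ADMA": MrmAssayConfig(
            "ADMA", "D7-ADMA", [0.2, 0.4, 1.0, 2.0, 5.0, 10.0],
            has_qualifier=False,
        ),
    }


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r2: float
    weighting: str
    n_levels: int
    accepted: bool


def is_normalize(quantifier_area: float, is_area: float) -> float:
    """Response ratio = quantifier area / internal-standard area."""
    if is_area <= 0:
        raise ValueError(f"is_area must be > 0 (got {is_area})")
    return quantifier_area / is_area


def _fit_weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if np.any(x <= 0):
        raise ValueError("1/x weighting needs strictly positive levels")
    return 1.0 / x if weighting == "1/x" else 1.0 / x**2


def fit_calibration(
    levels: list[tuple[float, float]],
    weighting: str = "1/x",
    r2_min: float = 0.99,
    analyte: str = "",
) -> CalibrationCurve:
    """Weighted least-squares calibration line through (nominal, response).

    r-squared is that of the weighted fit (1 - weighted RSS / weighted TSS
    about the weighted mean).  The curve is accepted when r2 > ``r2_min``
    and at least 4 distinct levels entered the fit.
    """
    x = np.asarray([lv for lv, _ in levels], dtype=float)
    y = np.asarray([r for _, r in levels], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration is rank deficient (single level)")
    w = _fit_weights(x, weighting)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = model.params
    r2 = float(model.rsquared)
    n_levels = int(np.unique(x).size)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        weighting=weighting,
        n_levels=n_levels,
        accepted=bool(r2 > r2_min and n_levels >= 4),
    )


def back_calculate(
    response_ratio: float,
    curve: CalibrationCurve,
    lloq: float,
    uloq: float,
) -> tuple[float, set[str]]:
    """Concentration from a response ratio through an accepted curve.

    Values exactly at the LLOQ or ULOQ pass unflagged (inclusive limits);
    outside they are still reported numerically but flagged.
    """
    if not curve.accepted:
        raise ValueError(f"curve for {curve.analyte!r} not accepted")
    if curve.slope == 0:
        raise ValueError("zero calibration slope")
    conc = (response_ratio - curve.intercept) / curve.slope
    flags: set[str] = set()
    if conc < lloq:
        flags.add(FLAG_BELOW_LLOQ)
    elif conc > uloq:
        flags.add(FLAG_ABOVE_ULOQ)
    return float(conc), flags


def ion_ratio_qc(
    ion_ratios: np.ndarray | list[float],
    reference_mean: float,
    tolerance: float = 0.15,
) -> np.ndarray:
    """Boolean fail mask: relative deviation from the reference mean > tolerance."""
    if reference_mean <= 0:
        raise ValueError("reference mean ion ratio must be > 0")
    ratios = np.asarray(ion_ratios, dtype=float)
    return np.abs(ratios - reference_mean) / reference_mean > tolerance


def batch_accept(
    pooled_concentrations: list[float],
    nominal_mean: float | None,
    cv_max: float = 0.15,
    bias_max: float = 0.15,
) -> tuple[bool | None, float, float]:
    """Pooled-serum batch gate: imprecision (CV) and inaccuracy (bias) < 15%.

    Returns ``(accepted, cv, bias)``.  With fewer than two pooled values the
    verdict is None (unknown) with a warning; without a nominal the bias gate
    is skipped (bias = nan).
    """
    pooled = np.asarray(pooled_concentrations, dtype=float)
    if pooled.size < 2:
        warnings.warn(
            "no pooled samples"
            if pooled.size == 0
            else "only one pooled sample: batch acceptance unknown",
            stacklevel=2,
        )
        return None, float("nan"), float("nan")
    mean = pooled.mean()
    cv = float(pooled.std(ddof=1) / mean)
    if nominal_mean is None:
        warnings.warn(
            "no pooled nominal configured: bias gate skipped", stacklevel=2
        )
        bias = float("nan")
        return bool(cv < cv_max), cv, bias
    bias = float(abs(mean - nominal_mean) / nominal_mean)
    return bool(cv < cv_max and bias < bias_max), cv, bias


def quantify_batch(
    batch: pd.DataFrame,
    configs: dict[str, MrmAssayConfig] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full quantitation workflow on one batch table.

    ``batch`` follows the schema ``sample_id, role, analyte, quantifier_area,
    qualifier_area, is_area, nominal_conc``.  Returns

    * a concentration table (sample_id, role, analyte, concentration_uM,
      flags) for every non-calibrator injection, and
    * a per-analyte QC report (slope, intercept, r2, curve_accepted,
      pooled_cv, pooled_bias, batch_accepted).

    Rows of an unaccepted batch (or unaccepted curve) keep a ``batch_failed``
    flag so no concentration is reported silently.
    """
    configs = configs if configs is not None else default_assay_configs()
    conc_rows, qc_rows = [], []
    for analyte, sub in batch.groupby("analyte", sort=True):
        if analyte not in configs:
            raise KeyError(f"no assay config for analyte {analyte!r}")
        cfg = configs[analyte]

        cal = sub[sub["role"] == "calibrator"].copy()
        cal = cal[~cal["nominal_conc"].isin(cfg.masked_levels)]
        cal = cal[cal["is_area"] > 0]
        levels = [
            (float(r.nominal_conc), is_normalize(r.quantifier_area, r.is_area))
            for r in cal.itertuples()
        ]
        curve = fit_calibration(
            levels, weighting=cfg.weighting, r2_min=cfg.r2_min, analyte=analyte
        )

        # reference quantifier/qualifier ratio from calibrator standards
        ref_ion_ratio = None
        if cfg.has_qualifier:
            qual = cal[cal["qualifier_area"] > 0]
            if len(qual):
                ref_ion_ratio = float(
                    (qual["quantifier_area"] / qual["qualifier_area"]).mean()
                )

        measured = sub[sub["role"] != "calibrator"]
        pooled_conc = []
        analyte_rows = []
        for r in measured.itertuples():
            flags: set[str] = set()
            conc = float("nan")
            if not r.is_area > 0:
                flags.add(FLAG_NO_IS)
            elif curve.accepted:
                ratio = is_normalize(r.quantifier_area, r.is_area)
                conc, flags = back_calculate(ratio, curve, cfg.lloq, cfg.uloq)
            if (
                cfg.has_qualifier
                and ref_ion_ratio is not None
                and np.isfinite(r.qualifier_area)
                and r.qualifier_area > 0
            ):
                ion_ratio = r.quantifier_area / r.qualifier_area
                if ion_ratio_qc([ion_ratio], ref_ion_ratio,
                                cfg.ion_ratio_tolerance)[0]:
                    flags.add(FLAG_ION_RATIO)
            if r.role == "pooled" and np.isfinite(conc):
                pooled_conc.append(conc)
            analyte_rows.append(
                {
                    "sample_id": r.sample_id,
                    "role": r.role,
                    "analyte": analyte,
                    "concentration_uM": conc,
                    "flags": flags,
                }
            )

        accepted, cv, bias = batch_accept(
            pooled_conc, cfg.pooled_nominal, cfg.qc_cv_max, cfg.qc_bias_max
        )
        batch_ok = curve.accepted and accepted is True
        if not batch_ok:
            for row in analyte_rows:
                row["flags"].add(FLAG_BATCH)
        conc_rows.extend(analyte_rows)
        qc_rows.append(
            {
                "analyte": analyte,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r2": curve.r2,
                "curve_accepted": curve.accepted,
                "n_pooled": len(pooled_conc),
                "pooled_cv": cv,
                "pooled_bias": bias,
                "batch_accepted": batch_ok,
            }
        )

    conc = pd.DataFrame(
        conc_rows,
        columns=["sample_id", "role", "analyte", "concentration_uM", "flags"],
    )
    conc["flags"] = conc["flags"].map(lambda s: ";".join(sorted(s)))
    qc = pd.DataFrame(qc_rows).set_index("analyte")
    return conc, qc
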
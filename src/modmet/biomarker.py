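"""Group comparison and ROC evaluation of metabolite biomarkers.

Concentrations from the quantitation stage are compared across clinical
groups with the two-sided Mann-Whitney test (the same U machinery as the
expression scoring), and classifier performance of single analytes and
analyte ratios (the SDMA/arginine ratio in particular) is summarized by the
area under the ROC curve.  Because the ratio's numerator rises and its
denominator falls in disease, the ratio typically separates cases from
controls better than either analyte alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .modscore import u_statistics

__all__ = [
    "RocResult",
    "PanelSpec",
    "compute_ratio",
    "group_test",
    "roc",
    "panel_report",
    "build_biomarker_table",
]


@dataclass
class RocResult:
    """ROC curve and area for one marker.

    ``direction`` records which orientation scored as "case": ``case_high``
    (larger values indicate case) or ``case_low``.  The curve runs from
    (0, 0) to (1, 1) with ties collapsed to single operating points, and
    ``auc`` is its trapezoidal area.
    """

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_case: int
    n_control: int
    direction: str

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def compute_ratio(
    numerator, denominator, lloq_policy: str = "keep"
) -> np.ndarray:
    """Elementwise concentration ratio.

    Samples with a non-positive denominator are excluded (NaN) with a
    warning.  ``lloq_policy`` is carried by callers that track below-LLOQ
    flags; the ratio itself is computed for every valid pair.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator lengths differ")
    if lloq_policy not in ("keep", "drop"):
        raise ValueError(f"unknown lloq_policy {lloq_policy!r}")
    bad = ~(den > 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} sample(s) excluded: denominator <= 0",
            stacklevel=2,
        )
    out = np.full(num.shape, np.nan)
    out[~bad] = num[~bad] / den[~bad]
    return out


def group_test(
    values, labels, case_label: str, control_label: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test of case vs control values: ``(u1, p)``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    case = values[labels == case_label]
    control = values[labels == control_label]
    if case.size == 0 or control.size == 0:
        raise ValueError(
            f"empty group: {case_label}={case.size}, {control_label}={control.size}"
        )
    u1, _u2, p = u_statistics(case, control)
    return u1, p


def roc(
    values,
    labels,
    case_label: str,
    control_labels: str | list[str],
    direction: str = "auto",
) -> RocResult:
    """ROC curve of ``values`` classifying case vs the pooled control set.

    Thresholds sweep the unique values (ties form one operating point); the
    AUC is the trapezoidal area.  With ``direction='auto'`` the orientation
    is chosen so that auc >= 0.5 and reported; ``'case_high'``/``'case_low'``
    fix it.  NaN values are dropped.  All-identical values give a degenerate
    diagonal curve with auc 0.5 and a warning.
    """
    if isinstance(control_labels, str):
        control_labels = [control_labels]
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values) & (
        (labels == case_label) | np.isin(labels, control_labels)
    )
    v, lab = values[keep], labels[keep]
    y = (lab == case_label).astype(int)
    n_case, n_control = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("need at least one case and one control")

    def _curve(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        if np.ptp(scores) == 0:
            warnings.warn("all values identical: degenerate ROC", stacklevel=3)
            return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
        fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
        return fpr, tpr, float(np.trapezoid(tpr, fpr))

    fpr, tpr, auc = _curve(v)
    chosen = "case_high"
    if direction == "case_low" or (direction == "auto" and auc < 0.5):
        fpr, tpr, auc = _curve(-v)
        chosen = "case_low"
    elif direction not in ("auto", "case_high", "case_low"):
        raise ValueError(f"unknown direction {direction!r}")
    return RocResult(
        auc=auc, fpr=fpr, tpr=tpr, n_case=n_case, n_control=n_control,
        direction=chosen,
    )


@dataclass
class PanelSpec:
    """Which markers to evaluate against which case/control label sets.

    ``markers`` may name analyte columns or ratios written ``"A/B"``.
    Each entry of ``control_sets`` is a list of control labels pooled into
    one comparison (e.g. ``["normal"]`` and ``["normal", "benign"]``).
    """

    markers: list[str] = field(
        default_factory=lambda: ["SDMA", "ARG", "SDMA/ARG"]
    )
    case_labels: list[str] = field(default_factory=lambda: ["OC"])
    control_sets: list[list[str]] = field(
        default_factory=lambda: [["normal"], ["normal", "benign"]]
    )
    direction: str = "auto"
    lloq_policy: str = "keep"


def build_biomarker_table(
    concentrations: pd.DataFrame, labels: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Pivot a tidy concentration table to one row per sample, plus labels.

    ``concentrations`` needs columns sample_id, analyte, concentration_uM;
    below-LLOQ rows are kept (the panel's ``lloq_policy`` decides their fate).
    """
    wide = concentrations.pivot_table(
        index="sample_id", columns="analyte", values="concentration_uM",
        aggfunc="first", dropna=False,
    )
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    wide.insert(0, "group", lab.reindex(wide.index))
    missing = wide.index[wide["group"].isna()]
    if len(missing):
        warnings.warn(
            f"{len(missing)} sample(s) without clinical label dropped",
            stacklevel=2,
        )
        wide = wide.dropna(subset=["group"])
    return wide


def _marker_values(table: pd.DataFrame, marker: str) -> np.ndarray:
    if "/" in marker:
        num_name, den_name = marker.split("/", 1)
        for name in (num_name, den_name):
            if name not in table.columns:
                raise KeyError(f"unknown analyte {name!r} in marker {marker!r}")
        return compute_ratio(table[num_name], table[den_name])
    if marker not in table.columns:
        raise KeyError(f"unknown analyte {marker!r}")
    return table[marker].to_numpy(dtype=float)


def panel_report(table: pd.DataFrame, panel: PanelSpec) -> pd.DataFrame:
    """Evaluate every marker of a panel against every control set.

    For each (marker, control set): group medians, Mann-Whitney u and p, AUC
    and scoring direction.  Rows are ranked by AUC within each comparison.
    The case set is the union of ``panel.case_labels``.
    """
    labels = table["group"].astype(str).to_numpy()
    case_mask = np.isin(labels, panel.case_labels)
    if not case_mask.any():
        raise ValueError(
            f"no case samples for labels {panel.case_labels} "
            f"(groups present: {sorted(set(labels))})"
        )
    merged_labels = np.where(case_mask, "__case__", labels)
    rows = []
    for controls in panel.control_sets:
        comp_name = "+".join(panel.case_labels) + "_vs_" + "+".join(controls)
        for marker in panel.markers:
            values = _marker_values(table, marker)
            ctrl_mask = np.isin(labels, controls)
            ok = np.isfinite(values)
            case_vals = values[case_mask & ok]
            ctrl_vals = values[ctrl_mask & ok]
            if case_vals.size == 0 or ctrl_vals.size == 0:
                raise ValueError(
                    f"marker {marker!r}, comparison {comp_name}: empty group "
                    f"after filtering (n_case={case_vals.size}, "
                    f"n_control={ctrl_vals.size})"
                )
            u1, _u2, p = u_statistics(case_vals, ctrl_vals)
            merged = np.where(ctrl_mask, "__ctrl__", merged_labels)
            res = roc(values, merged, "__case__", "__ctrl__",
                      direction=panel.direction)
            rows.append(
                {
                    "marker": marker,
                    "comparison": comp_name,
                    "n_case": res.n_case,
                    "n_control": res.n_control,
                    "median_case": float(np.median(case_vals)),
                    "median_control": float(np.median(ctrl_vals)),
                    "u": u1,
                    "p": p,
                    "auc": res.auc,
                    "direction": res.direction,
                }
            )
    report = pd.DataFrame(rows)
    return (
        report.sort_values(["comparison", "auc"], ascending=[True, False])
        .reset_index(drop=True)
    )
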
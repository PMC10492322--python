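"""Truth-known simulators for expression matrices and targeted-MRM batches.

Two generators cover the pipeline's two halves:

* :func:`simulate_expression` draws a log2-scale expression matrix for a
  multi-group cohort (normal / benign / early-stage / late-stage by default,
  with the tissue-cohort group sizes 71 / 8 / 280 / 1016) and plants additive
  log2 shifts into chosen functional modules for chosen two-group
  comparisons, so module recovery and FDR calibration can be checked against
  known truth.

* :func:`simulate_mrm_batch` emits an LC-MS/MS multiple-reaction-monitoring
  batch table: six-level calibrators, pooled-serum QC injections, and unknown
  serum samples with group-dependent true concentrations.  Serum injections
  experience matrix signal suppression (default 25-52%) applied equally to
  analyte and internal-standard areas — the mechanism that IS normalization
  cancels.  Injection-level drift likewise scales both areas of an
  injection; ``tech_cv`` is the residual analytical CV of the IS-normalized
  response ratio, matching how assay precision is reported.

Both generators are byte-deterministic under a fixed seed and return tidy
ground-truth tables (entity id, comparison or analyte, true value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modscore import ExpressionDataset

__all__ = [
    "ExpressionSimSpec",
    "AnalyteSim",
    "MrmSimSpec",
    "simulate_expression",
    "simulate_mrm_batch",
]


# ---------------------------------------------------------------------------
# Expression simulator
# ---------------------------------------------------------------------------

DEFAULT_GROUP_SIZES = {"normal": 71, "benign": 8, "early": 280, "late": 1016}

#: The two scored contrasts; benign is carried as a label but not contrasted.
DEFAULT_COMPARISONS = (("early", "normal"), ("late", "early"))


@dataclass
class ExpressionSimSpec:
    """Parameters of a planted-module expression simulation.

    ``planted_effects`` maps ``(module_id, (case_label, control_label))`` to a
    log2 shift added to the case group's mean for that module's genes.
    ``modules`` maps module id -> gene index set (subset of ``range(n_genes)``).
    """

    n_genes: int = 1000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    modules: dict[str, list[int]] = field(default_factory=dict)
    planted_effects: dict[tuple[str, tuple[str, str]], float] = field(
        default_factory=dict
    )
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    gene_baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} must have >= 2 samples (got {n})")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for mod_id, genes in self.modules.items():
            bad = [g for g in genes if not 0 <= int(g) < self.n_genes]
            if bad:
                raise ValueError(
                    f"module {mod_id!r} gene indices out of range: {bad[:5]}"
                )
        for (mod_id, (case, ctrl)) in self.planted_effects:
            if mod_id not in self.modules:
                raise ValueError(f"planted effect for unknown module {mod_id!r}")
            for lab in (case, ctrl):
                if lab not in self.group_sizes:
                    raise ValueError(f"planted effect names unknown group {lab!r}")


def _per_gene_shifts(spec: ExpressionSimSpec) -> dict[tuple[str, str], np.ndarray]:
    """Resolve module-level planted effects to per-gene shifts per comparison.

    A gene reached by two modules with *different* shifts for the same
    comparison is contradictory and rejected by name.
    """
    shifts: dict[tuple[str, str], np.ndarray] = {}
    owner: dict[tuple[str, str], dict[int, str]] = {}
    for (mod_id, comp), effect in spec.planted_effects.items():
        vec = shifts.setdefault(comp, np.zeros(spec.n_genes))
        own = owner.setdefault(comp, {})
        for g in spec.modules[mod_id]:
            g = int(g)
            if g in own and vec[g] != effect:
                raise ValueError(
                    f"gene {g} receives contradictory planted effects for "
                    f"comparison {comp}: {vec[g]} (module {own[g]!r}) vs "
                    f"{effect} (module {mod_id!r})"
                )
            vec[g] = effect
            own[g] = mod_id
    return shifts


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw a truth-known log2 expression matrix.

    Per gene, a baseline log2 abundance is drawn around ``baseline_mean``;
    per gene x sample, i.i.d. Gaussian noise of SD ``noise_sd`` is added on
    the log2 scale.  Planted effects add their shift to the case group's mean.
    Returns the dataset and a tidy truth table with one row per
    (module, comparison) giving the true planted shift (0 when none).
    """
    spec.validate()
    shifts = _per_gene_shifts(spec)
    rng = np.random.default_rng(spec.seed)

    groups = list(spec.group_sizes)
    sample_ids, labels = [], {}
    for g in groups:
        for k in range(spec.group_sizes[g]):
            sid = f"{g}_{k + 1:04d}"
            sample_ids.append(sid)
            labels[sid] = g

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    baseline = spec.baseline_mean + rng.normal(
        0.0, spec.gene_baseline_sd, size=spec.n_genes
    )
    n_samples = len(sample_ids)
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_samples)
    )
    col_group = np.asarray([labels[s] for s in sample_ids])
    for (case, _ctrl), vec in shifts.items():
        values[:, col_group == case] += vec[:, None]

    dataset = ExpressionDataset(gene_ids, sample_ids, values, labels, log2=True)

    comparisons = {comp for (_m, comp) in spec.planted_effects}
    comparisons.update(
        c for c in DEFAULT_COMPARISONS
        if c[0] in spec.group_sizes and c[1] in spec.group_sizes
    )
    truth_rows = [
        {
            "entity_id": mod_id,
            "comparison": f"{case}_vs_{ctrl}",
            "true_value": spec.planted_effects.get((mod_id, (case, ctrl)), 0.0),
        }
        for mod_id in spec.modules
        for (case, ctrl) in sorted(comparisons)
    ]
    truth = pd.DataFrame(truth_rows, columns=["entity_id", "comparison", "true_value"])
    return dataset, truth


def module_gmt(spec: ExpressionSimSpec) -> dict[str, list[str]]:
    """Module definitions of a simulation as gene-id lists (GMT-ready)."""
    return {
        mod_id: [f"G{int(i):05d}" for i in genes]
        for mod_id, genes in spec.modules.items()
    }


# ---------------------------------------------------------------------------
# MRM batch simulator
# ---------------------------------------------------------------------------

@dataclass
class AnalyteSim:
    """True assay behaviour of one analyte in the simulator.

    ``slope``/``intercept`` define the true response-ratio line
    (response ratio per µM); ``ion_ratio`` is the true quantifier/qualifier
    area ratio, or None for analytes without a qualifier transition.
    """

    name: str
    calibrator_levels: list[float]
    lloq: float
    slope: float
    intercept: float = 0.0
    ion_ratio: float | None = None
    is_name: str = ""
    is_base_area: float = 1.0e5


def _default_analytes() -> list[AnalyteSim]:
    # six-level calibrators: 0.20-10.0 uM for SDMA/ADMA, 4.00-200 uM arginine;
    # ADMA/SDMA carry no qualifier transition
    return [
        AnalyteSim("ARG", [4.0, 8.0, 20.0, 40.0, 100.0, 200.0], lloq=4.0,
                   slope=0.012, intercept=0.0, ion_ratio=3.0,
                   is_name="13C6-ARG"),
        AnalyteSim("SDMA", [0.2, 0.4, 1.0, 2.0, 5.0, 10.0], lloq=0.2,
                   slope=0.40, intercept=0.0, ion_ratio=None,
                   is_name="D7-ADMA"),
        AnalyteSim("ADMA", [0.2, 0.4, 1.0, 2.0, 5.0, 10.0], lloq=0.2,
                   slope=0.40, intercept=0.0, ion_ratio=None,
                   is_name="D7-ADMA"),
    ]


def _default_group_conc() -> dict[tuple[str, str], float]:
    # serum means in uM: SDMA elevated and arginine depressed in cases,
    # ADMA unchanged; benign tracks normal
    return {
        ("normal", "ARG"): 80.0, ("benign", "ARG"): 78.0, ("OC", "ARG"): 50.0,
        ("normal", "SDMA"): 0.55, ("benign", "SDMA"): 0.58, ("OC", "SDMA"): 1.10,
        ("normal", "ADMA"): 0.60, ("benign", "ADMA"): 0.60, ("OC", "ADMA"): 0.60,
    }


@dataclass
class MrmSimSpec:
    """Parameters of a simulated MRM quantitation batch.

    Defaults emulate the blood-cohort design: 464 normal, 3 benign and 13
    ovarian-cancer unknowns, pooled-serum QC injections at 10% of the unknown
    count, 25-52% matrix suppression, 5% technical CV and 25% biological CV.
    """

    analytes: list[AnalyteSim] = field(default_factory=_default_analytes)
    group_conc: dict[tuple[str, str], float] = field(
        default_factory=_default_group_conc
    )
    conc_cv: float = 0.25
    suppression_range: tuple[float, float] = (0.25, 0.52)
    tech_cv: float = 0.05
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"normal": 464, "benign": 3, "OC": 13}
    )
    n_pooled: int | None = None  # None -> 10% of unknowns
    pooled_conc: dict[str, float] | None = None  # None -> normal-group mean
    seed: int = 0

    def validate(self) -> None:
        for a in self.analytes:
            lv = np.asarray(a.calibrator_levels, dtype=float)
            if not np.all(np.diff(lv) > 0):
                raise ValueError(f"{a.name}: calibrator levels must increase")
        lo, hi = self.suppression_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("suppression fractions must satisfy 0 <= lo <= hi < 1")
        if self.conc_cv < 0 or self.tech_cv < 0:
            raise ValueError("CVs must be >= 0")
        for g in self.n_per_group:
            for a in self.analytes:
                if (g, a.name) not in self.group_conc:
                    raise ValueError(
                        f"group_conc missing entry for group {g!r}, "
                        f"analyte {a.name!r}"
                    )


def _lognoise(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def simulate_mrm_batch(spec: MrmSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit one MRM batch table plus ground-truth concentrations.

    The batch table has one row per (injection, analyte) with columns
    ``sample_id, role, analyte, quantifier_area, qualifier_area, is_area,
    nominal_conc``.  Calibrators are matrix-free (no suppression); pooled and
    unknown serum injections share one suppression factor per
    (sample, analyte) applied to both the quantifier and the IS area.
    Truth rows carry each serum sample's true concentration per analyte.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_unknown = sum(spec.n_per_group.values())
    n_pooled = (
        spec.n_pooled if spec.n_pooled is not None else int(round(0.10 * n_unknown))
    )

    samples: list[tuple[str, str, str | None]] = []  # (sample_id, role, group)
    for k in range(max(len(a.calibrator_levels) for a in spec.analytes)):
        samples.append((f"CAL{k + 1}", "calibrator", None))
    for k in range(n_pooled):
        samples.append((f"POOL{k + 1:03d}", "pooled", None))
    for g, n in spec.n_per_group.items():
        for k in range(n):
            samples.append((f"{g}_{k + 1:04d}", "unknown", g))

    # true concentrations per serum sample x analyte
    truth_rows = []
    true_conc: dict[tuple[str, str], float] = {}
    for a in spec.analytes:
        pooled_level = (
            spec.pooled_conc[a.name]
            if spec.pooled_conc is not None
            else spec.group_conc[("normal", a.name)]
        )
        for sid, role, grp in samples:
            if role == "pooled":
                true_conc[(sid, a.name)] = pooled_level
            elif role == "unknown":
                mean = spec.group_conc[(grp, a.name)]
                c = mean * _lognoise(rng, spec.conc_cv)
                true_conc[(sid, a.name)] = float(c)
        truth_rows.extend(
            {"entity_id": sid, "analyte": a.name,
             "true_value": true_conc[(sid, a.name)]}
            for sid, role, _ in samples if role in ("pooled", "unknown")
        )

    # one suppression factor per serum sample x analyte
    lo, hi = spec.suppression_range
    suppression = {
        (sid, a.name): float(rng.uniform(lo, hi))
        for sid, role, _ in samples if role in ("pooled", "unknown")
        for a in spec.analytes
    }

    rows = []
    for sid, role, _grp in samples:
        for a in spec.analytes:
            if role == "calibrator":
                k = int(sid[3:]) - 1
                if k >= len(a.calibrator_levels):
                    continue
                conc = a.calibrator_levels[k]
                nominal = conc
                supp = 0.0
            else:
                conc = true_conc[(sid, a.name)]
                nominal = np.nan
                supp = suppression[(sid, a.name)]
            response = a.slope * conc + a.intercept
            # injection-level drift hits analyte and IS alike and cancels in
            # the ratio; tech_cv is the analytical CV of the response ratio
            injection = (1 - supp) * _lognoise(rng, spec.tech_cv)
            is_area = a.is_base_area * injection
            quant_area = (
                response * a.is_base_area * injection
                * _lognoise(rng, spec.tech_cv)
            )
            if a.ion_ratio is not None:
                qual_area = quant_area / a.ion_ratio * _lognoise(
                    rng, spec.tech_cv
                )
            else:
                qual_area = np.nan
            rows.append(
                {
                    "sample_id": sid,
                    "role": role,
                    "analyte": a.name,
                    "quantifier_area": quant_area,
                    "qualifier_area": qual_area,
                    "is_area": is_area,
                    "nominal_conc": nominal,
                }
            )

    batch = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "role", "analyte", "quantifier_area",
            "qualifier_area", "is_area", "nominal_conc",
        ],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["entity_id", "analyte", "true_value"]
    )
    return batch, truth
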
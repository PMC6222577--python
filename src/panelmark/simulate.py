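"""Synthetic strain-panel and case-control cohort generators with known truth.

The panel generator emulates a paired control/treated expression study across
a large inbred mouse strain panel: each strain contributes replicate arrays in
both arms, a subset of probes carries a planted log2 fold change in the
treated arm, and a quantitative remodeling trait (change in left ventricular
internal dimension, mm) is built as a noisy linear function of the realized
treated-arm strain means of a subset of "trait" probes.  Probes planted in
both subsets are the ground-truth overlay candidates.

The cohort generator emulates a retrospective case-control biomarker study:
case/control labels are fixed first (ascertainment), then the biomarker and
covariates are drawn per group.  Case-group distributions are exponential
tilts of the control-group distributions, ``f_case(x) ∝ exp(beta * x) *
f_control(x)``, which makes the draw exactly consistent with a prospective
logistic model with the planted log-odds coefficients ``beta`` — so logistic
fits on the generated data are estimating a well-defined true parameter.
For a Gaussian covariate the tilt shifts the mean by ``beta * sigma**2``;
for a Bernoulli covariate it multiplies the odds by ``exp(beta)``; for the
lognormal biomarker the tilt acts on the log scale, so the planted biomarker
coefficient is per log-ng/mL unit.

A single seed is split deterministically across the two sub-generators, so
panel and cohort draws are independent but jointly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import ExpressionPanel, write_annotation, write_cohort, write_expression, write_trait


@dataclass
class GeneratorConfig:
    """All knobs of both generators; defaults are the emulated study's design.

    Panel defaults: 91 strains, 2 replicates per arm, planted fold changes on
    the scale of the printed top-DE table (|logFC| 1.0-2.0), log2 expression
    noise SD 0.5, and trait weights scaled so the planted transcript-trait
    correlations land near ``trait_r_target`` (0.37, mid-range of the printed
    top-correlation table).  Cohort defaults: 119 cases / 270 controls with a
    protective biomarker (case mean 0.74 vs control 1.20 ng/mL) and covariate
    effects in the directions of the published logistic table.
    """

    # --- strain panel ---
    n_strains: int = 91
    n_probes: int = 300
    replicates_per_arm: int = 2
    n_de: int = 20
    n_trait: int = 5
    n_overlap: int = 2
    n_duplicate_symbols: int = 1
    logfc_range: tuple[float, float] = (1.0, 2.0)
    down_fraction: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    expr_noise_sd: float = 0.5
    strain_effect_sd: float = 0.0
    trait_weight: float = 0.25
    trait_r_target: float = 0.37
    trait_noise_sd: float | None = None
    trait_intercept: float = 0.5

    # --- case-control cohort ---
    n_cases: int = 119
    n_controls: int = 270
    control_biomarker_mean: float = 1.20
    control_biomarker_sd: float = 0.26
    case_biomarker_mean: float = 0.74
    biomarker_beta: float | None = None
    continuous_covariates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # name: (control mean, SD, odds ratio per unit)
            "age_yr": (58.0, 7.0, 1.15),
            "bmi_kg_m2": (27.0, 4.0, 1.12),
            "egfr": (90.0, 15.0, 0.975),
            "ldl_mg_dl": (140.0, 35.0, 0.985),
        }
    )
    binary_covariates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # name: (control prevalence, odds ratio)
            "htn": (0.25, 5.0),
            "dm": (0.06, 8.0),
        }
    )
    include_probnp: bool = True
    probnp_n: int = 42

    seed: int = 0

    # ------------------------------------------------------------------
    def validate_panel(self) -> None:
        for name in ("n_strains", "n_probes", "replicates_per_arm"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_strains < 4:
            raise ConfigurationError(
                f"n_strains must be >= 4 for correlation stages, got {self.n_strains}"
            )
        for name in ("n_de", "n_trait", "n_overlap", "n_duplicate_symbols"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_overlap > min(self.n_de, self.n_trait):
            raise ConfigurationError(
                "n_overlap exceeds min(n_de, n_trait); cannot plant overlap candidates"
            )
        if self.n_de + self.n_trait - self.n_overlap > self.n_probes:
            raise ConfigurationError("n_probes too small for requested planted sets")
        if self.n_overlap + 2 * self.n_duplicate_symbols > self.n_de:
            raise ConfigurationError(
                "n_duplicate_symbols needs 2 non-overlap planted DE probes each"
            )
        if self.expr_noise_sd <= 0:
            raise ConfigurationError(f"expr_noise_sd must be > 0, got {self.expr_noise_sd}")
        if self.strain_effect_sd < 0:
            raise ConfigurationError("strain_effect_sd must be >= 0")
        lo, hi = self.logfc_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo <= 0 or hi < lo:
            raise ConfigurationError(f"logfc_range must be finite with 0 < lo <= hi, got {self.logfc_range}")
        if self.trait_noise_sd is None:
            if not 0 < self.trait_r_target < 1:
                raise ConfigurationError("trait_r_target must be in (0, 1)")
            if self.n_trait > 0 and self.n_trait * self.trait_r_target**2 >= 1:
                raise ConfigurationError(
                    "trait_r_target unreachable: n_trait * r^2 must be < 1"
                )
        elif self.trait_noise_sd < 0:
            raise ConfigurationError("trait_noise_sd must be >= 0")

    def validate_cohort(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigurationError(
                f"n_cases and n_controls must be >= 2, got {self.n_cases}/{self.n_controls}"
            )
        if self.control_biomarker_mean <= 0 or self.case_biomarker_mean <= 0:
            raise ConfigurationError("biomarker group means must be > 0 (lognormal)")
        if self.control_biomarker_sd <= 0:
            raise ConfigurationError(
                f"control_biomarker_sd must be > 0, got {self.control_biomarker_sd}"
            )
        for name, (_, sd, _) in self.continuous_covariates.items():
            if sd <= 0:
                raise ConfigurationError(f"continuous covariate {name}: sd must be > 0")
        for name, (prev, _) in self.binary_covariates.items():
            if not 0 < prev < 1:
                raise ConfigurationError(
                    f"binary covariate {name}: control prevalence must be in (0, 1)"
                )
        if self.include_probnp and self.probnp_n > self.n_cases:
            raise ConfigurationError("probnp_n cannot exceed n_cases")

    # strain-mean variance of a single probe (signal available to the trait)
    def _strain_mean_var(self) -> float:
        return self.strain_effect_sd**2 + self.expr_noise_sd**2 / self.replicates_per_arm

    def derived_trait_noise_sd(self) -> float:
        """Trait noise SD implied by the target per-probe correlation.

        With K equally weighted trait probes whose strain means have variance
        sigma_m^2, the population correlation between the trait and one probe
        is ``r = w*sigma_m / sqrt(K*w^2*sigma_m^2 + sigma_eps^2)``; solving
        for sigma_eps at ``r = trait_r_target`` gives the default.
        """
        if self.trait_noise_sd is not None:
            return self.trait_noise_sd
        if self.n_trait == 0:
            return 0.1
        var_m = self._strain_mean_var()
        w2 = self.trait_weight**2
        return math.sqrt(w2 * var_m * (1.0 / self.trait_r_target**2 - self.n_trait))


@dataclass
class PanelTruth:
    """Ground truth of a simulated panel (planted probes and effect sizes)."""

    de_genes: set[str]
    trait_genes: set[str]
    planted_logfc: dict[str, float]  # zero (absent) for unplanted probes
    planted_weights: dict[str, float]  # mm per log2 unit
    noise_sd_expr: float
    noise_sd_trait: float
    trait_intercept: float

    def logfc_of(self, probe: str) -> float:
        return self.planted_logfc.get(probe, 0.0)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``beta`` holds the prospective-model log-odds coefficients the draw is
    consistent with; the biomarker term is keyed ``log_biomarker`` (per
    log-ng/mL).  Group means are biomarker population means on the natural
    ng/mL scale.
    """

    beta: dict[str, float]
    case_mean: float
    control_mean: float
    case_n: int
    control_n: int


def _split_seed(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    panel_ss, cohort_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(panel_ss), np.random.default_rng(cohort_ss)


# ---------------------------------------------------------------------------
# strain panel
# ---------------------------------------------------------------------------

def simulate_panel(
    config: GeneratorConfig,
) -> tuple[ExpressionPanel, pd.DataFrame, pd.DataFrame, PanelTruth]:
    """Simulate a paired control/treated strain panel with planted truth.

    Returns ``(panel, annotation, trait, truth)``.  Every strain has
    ``replicates_per_arm`` samples in each arm; planted DE probes are shifted
    by their planted logFC in the treated arm; the trait is a noisy linear
    function of realized treated-arm strain means of the trait probes.
    """
    config.validate_panel()
    rng, _ = _split_seed(config.seed)

    n_probes, n_strains, reps = config.n_probes, config.n_strains, config.replicates_per_arm
    probe_ids = np.array([f"ILMN_SIM_{i:06d}" for i in range(1, n_probes + 1)])
    strains = [f"Strain_{i:03d}" for i in range(1, n_strains + 1)]

    # planted sets: overlap probes are both DE and trait-linked
    perm = rng.permutation(n_probes)
    n_extra_trait = config.n_trait - config.n_overlap
    de_idx = perm[: config.n_de]
    trait_idx = np.concatenate(
        [perm[: config.n_overlap], perm[config.n_de : config.n_de + n_extra_trait]]
    ).astype(int)

    # symbols: one per probe, except planted duplicate pairs sharing a symbol
    symbols = np.array([f"Gene{i:05d}" for i in range(1, n_probes + 1)], dtype=object)
    # duplicate pairs come from the non-overlap portion of the DE set so the
    # planted overlay candidates stay distinct symbols
    dup_pairs = []
    for k in range(config.n_duplicate_symbols):
        a, b = de_idx[config.n_overlap + 2 * k], de_idx[config.n_overlap + 2 * k + 1]
        symbols[b] = symbols[a]
        dup_pairs.append((a, b))

    # planted log2 fold changes; a minority are down-regulated
    logfc = np.zeros(n_probes)
    mags = rng.uniform(*config.logfc_range, size=config.n_de)
    signs = np.where(rng.random(config.n_de) < config.down_fraction, -1.0, 1.0)
    logfc[de_idx] = mags * signs
    for a, b in dup_pairs:  # duplicate probes of one symbol share the effect
        logfc[b] = logfc[a]

    # trait weights: equal magnitude, alternating sign (some probes correlate
    # negatively with the trait, as in the printed top-correlation table)
    weights = np.zeros(n_probes)
    wsigns = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(config.n_trait)])
    weights[trait_idx] = config.trait_weight * wsigns

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    strain_dev = (
        rng.normal(0.0, config.strain_effect_sd, size=(n_probes, n_strains))
        if config.strain_effect_sd > 0
        else np.zeros((n_probes, n_strains))
    )

    sample_ids, strain_col, arm_col, rep_col = [], [], [], []
    blocks = []
    for s_i, strain in enumerate(strains):
        mean_s = baseline + strain_dev[:, s_i]
        for arm, shift in (("control", 0.0), ("treated", 1.0)):
            for r in range(1, reps + 1):
                sample_ids.append(f"{strain}_{arm}_r{r}")
                strain_col.append(strain)
                arm_col.append(arm)
                rep_col.append(r)
                noise = rng.normal(0.0, config.expr_noise_sd, size=n_probes)
                blocks.append(mean_s + shift * logfc + noise)

    values = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        {"strain": strain_col, "treatment": arm_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    panel = ExpressionPanel(values=values, sample_meta=meta)

    # trait from realized treated-arm strain means of the trait probes
    treated_cols = meta.index[meta["treatment"] == "treated"]
    treated = values[treated_cols]
    strain_of = meta.loc[treated_cols, "strain"]
    strain_means = treated.T.groupby(strain_of.to_numpy()).mean().T  # probe x strain
    noise_sd_trait = config.derived_trait_noise_sd()
    signal = weights @ strain_means.loc[probe_ids].to_numpy()
    trait_vals = (
        config.trait_intercept
        + signal
        + rng.normal(0.0, noise_sd_trait, size=n_strains)
    )
    trait = pd.DataFrame({"strain": strain_means.columns, "trait_delta": trait_vals})

    annotation = pd.DataFrame(
        {"probe_id": probe_ids, "symbol": symbols, "species": "mouse"}
    )
    truth = PanelTruth(
        de_genes={str(p) for p in probe_ids[de_idx]},
        trait_genes={str(p) for p in probe_ids[trait_idx]},
        planted_logfc={str(p): float(f) for p, f in zip(probe_ids, logfc) if f != 0.0},
        planted_weights={str(p): float(w) for p, w in zip(probe_ids, weights) if w != 0.0},
        noise_sd_expr=config.expr_noise_sd,
        noise_sd_trait=noise_sd_trait,
        trait_intercept=config.trait_intercept,
    )
    return panel, annotation, trait, truth


# ---------------------------------------------------------------------------
# case-control cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a retrospective case-control biomarker cohort.

    Labels are fixed by design (``n_cases``/``n_controls``); the biomarker is
    lognormal and strictly positive; each covariate's case distribution is an
    exponential tilt of its control distribution, so the planted log-odds
    coefficients in ``truth.beta`` are exact prospective-model parameters.
    """
    config.validate_cohort()
    _, rng = _split_seed(config.seed)

    n_ca, n_co = config.n_cases, config.n_controls
    n = n_ca + n_co
    hf = np.concatenate([np.ones(n_ca, dtype=int), np.zeros(n_co, dtype=int)])

    # biomarker: lognormal matched to control natural-scale mean/SD
    m, s = config.control_biomarker_mean, config.control_biomarker_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    sigma = math.sqrt(sigma2)
    mu0 = math.log(m) - sigma2 / 2.0
    if config.biomarker_beta is not None:
        beta_b = config.biomarker_beta
    else:
        beta_b = math.log(config.case_biomarker_mean / m) / sigma2
    mu1 = mu0 + beta_b * sigma2  # exponential tilt on the log scale
    log_b = np.where(
        hf == 1, rng.normal(mu1, sigma, size=n), rng.normal(mu0, sigma, size=n)
    )

    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"M{i:04d}" for i in range(1, n + 1)]),
        "biomarker_ng_ml": np.exp(log_b),
        "hf_status": hf,
    }
    beta: dict[str, float] = {"log_biomarker": beta_b}

    for name, (mean0, sd, or_unit) in config.continuous_covariates.items():
        b = math.log(or_unit)
        mean1 = mean0 + b * sd**2
        cols[name] = np.where(
            hf == 1, rng.normal(mean1, sd, size=n), rng.normal(mean0, sd, size=n)
        )
        beta[name] = b
    for name, (prev0, or_) in config.binary_covariates.items():
        odds1 = or_ * prev0 / (1.0 - prev0)
        prev1 = odds1 / (1.0 + odds1)
        cols[name] = (
            rng.random(n) < np.where(hf == 1, prev1, prev0)
        ).astype(int)
        beta[name] = math.log(or_)

    cohort = pd.DataFrame(cols)
    if config.include_probnp:
        probnp = np.full(n, np.nan)
        case_rows = np.flatnonzero(hf == 1)
        picked = rng.choice(case_rows, size=min(config.probnp_n, n_ca), replace=False)
        probnp[picked] = np.exp(rng.normal(math.log(800.0), 0.8, size=picked.size))
        cohort["probnp"] = probnp

    truth = CohortTruth(
        beta=beta,
        case_mean=float(np.exp(mu1 + sigma2 / 2.0)),
        control_mean=float(np.exp(mu0 + sigma2 / 2.0)),
        case_n=n_ca,
        control_n=n_co,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------

def write_panel_bundle(
    out_dir: str | Path,
    panel: ExpressionPanel,
    annotation: pd.DataFrame,
    trait: pd.DataFrame,
    truth: PanelTruth,
) -> dict[str, Path]:
    """Write a simulated panel as the TSV bundle the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out / "expression.tsv",
        "meta": out / "sample_meta.tsv",
        "annot": out / "annotation.tsv",
        "trait": out / "trait.tsv",
        "truth": out / "panel_truth.yaml",
    }
    write_expression(panel, paths["expr"], paths["meta"])
    write_annotation(annotation, paths["annot"])
    write_trait(trait, paths["trait"])
    paths["truth"].write_text(
        yaml.safe_dump(
            {
                "de_genes": sorted(truth.de_genes),
                "trait_genes": sorted(truth.trait_genes),
                "planted_logfc": truth.planted_logfc,
                "planted_weights": truth.planted_weights,
                "noise_sd_expr": truth.noise_sd_expr,
                "noise_sd_trait": truth.noise_sd_trait,
                "trait_intercept": truth.trait_intercept,
            },
            sort_keys=True,
        )
    )
    return paths


def write_cohort_bundle(
    out_dir: str | Path, cohort: pd.DataFrame, truth: CohortTruth
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"cohort": out / "cohort.csv", "truth": out / "cohort_truth.yaml"}
    write_cohort(cohort, paths["cohort"])
    paths["truth"].write_text(
        yaml.safe_dump(
            {
                "beta": truth.beta,
                "case_mean": truth.case_mean,
                "control_mean": truth.control_mean,
                "case_n": truth.case_n,
                "control_n": truth.control_n,
            },
            sort_keys=True,
        )
    )
    return paths
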
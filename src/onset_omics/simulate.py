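"""Synthetic paired tumor-normal cohorts with known ground truth.

The generator emits the three dataset types the pipeline consumes —
a log2 expression matrix, a methylation beta matrix, and a clinical sample
sheet — built on the same statistical skeleton every downstream model
assumes: per-person random effects shared by the tumor and normal sample,
a fixed tissue (tumor - normal) effect on designated features, an extra
tissue effect confined to one onset group (the tissue x onset interaction),
and independent residual noise.  Methylation noise is added on the logit
scale and mapped back so beta values stay inside [0, 1].

Defaults emulate the study conditions this pipeline was designed around:
67 early-onset and 98 late-onset persons, gene-set-structured expression
effects of log2(1.09) in the early-onset group versus log2(1.14) in the
late-onset group, and clinical category proportions taken from the cohort's
published cross-tabulations.  Every run is reproducible from a single seed;
the expression, methylation and clinical sub-streams are derived by stable
named keys so adding one generator never perturbs another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    FeatureAnnotation,
    GeneSetCollection,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_expression",
    "simulate_methylation",
    "simulate_clinical",
]

# Clinical category proportions per onset group, taken from the cohort's
# published cross-tabulations (counts over 98 late-onset / 67 early-onset
# persons).
DEFAULT_CLINICAL_PROPORTIONS: dict[str, dict] = {
    "sex": {
        "categories": ["male", "female"],
        "LOCRC": [57 / 98, 41 / 98],
        "EOCRC": [39 / 67, 28 / 67],
    },
    "stage": {
        "categories": ["1", "2", "3"],
        "LOCRC": [30 / 98, 26 / 98, 42 / 98],
        "EOCRC": [7 / 67, 16 / 67, 44 / 67],
    },
    "lvi": {
        "categories": ["absent", "present"],
        "LOCRC": [71 / 98, 27 / 98],
        "EOCRC": [36 / 67, 31 / 67],
    },
    "pni": {
        "categories": ["absent", "present"],
        "LOCRC": [90 / 98, 8 / 98],
        "EOCRC": [53 / 67, 14 / 67],
    },
    "msi": {
        "categories": ["MSI", "MSS"],
        "LOCRC": [26 / 98, 72 / 98],
        "EOCRC": [15 / 67, 52 / 67],
    },
}

# 450K-style region-class composition: island/shore/shelf in the chip's
# proportions, with a deep-sea fraction of 176112/485577.
_ISS = np.array([150254.0, 112067.0, 47114.0])
_ISS = _ISS / _ISS.sum()
DEFAULT_DEEP_SEA_FRACTION = 176112.0 / 485577.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Expression values are log2 intensities
    ``mu + tissue effect (+ interaction) + person + error``; methylation
    beta values are ``expit(logit(baseline + delta) + person + error)``
    clipped to [0.001, 0.999].  ``interaction_effect_log2`` is the extra
    tumor-normal effect applied to late-onset persons only, so the true
    late-onset effect is ``tissue_effect_log2 + interaction_effect_log2``.
    """

    n_persons_per_group: dict[str, int] = field(
        default_factory=lambda: {"EOCRC": 67, "LOCRC": 98}
    )
    n_features: int = 600
    n_gene_sets: int = 5
    set_size: int = 12
    probes_per_gene: int = 1
    mu_log2: float = 8.0
    sigma_person: float = 1.0
    sigma_error: float = 0.5
    tissue_effect_log2: float = float(np.log2(1.09))
    interaction_effect_log2: float = float(np.log2(1.14) - np.log2(1.09))
    # Methylation block
    beta_baseline_range: tuple[float, float] = (0.2, 0.75)
    beta_delta: float = 0.2
    beta_delta_specific: float = 0.08
    frac_dml_common: float = 0.10
    frac_dml_eocrc_specific: float = 0.02
    frac_dml_locrc_specific: float = 0.04
    deep_sea_fraction: float = DEFAULT_DEEP_SEA_FRACTION
    sigma_person_logit: float = 0.25
    sigma_error_logit: float = 0.25
    # Clinical block
    clinical_proportions: dict[str, dict] = field(
        default_factory=lambda: {
            k: {kk: list(vv) if isinstance(vv, list) else vv
                for kk, vv in v.items()}
            for k, v in DEFAULT_CLINICAL_PROPORTIONS.items()
        }
    )
    drop_normal_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma_person", "sigma_error", "sigma_person_logit",
                     "sigma_error_logit"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.beta_baseline_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("beta_baseline_range must be within [0, 1]")
        for delta in (self.beta_delta, self.beta_delta_specific):
            if hi + abs(delta) > 1.0 or lo - abs(delta) < 0.0:
                raise ValidationError(
                    "beta deltas push expected beta outside [0, 1]"
                )
        fracs = (self.frac_dml_common + self.frac_dml_eocrc_specific
                 + self.frac_dml_locrc_specific)
        if fracs > 1.0:
            raise ValidationError("DML fractions exceed 1")
        if not (0.0 <= self.deep_sea_fraction < 1.0):
            raise ValidationError("deep_sea_fraction must be in [0, 1)")
        if not (0.0 <= self.drop_normal_fraction < 1.0):
            raise ValidationError("drop_normal_fraction must be in [0, 1)")
        for cov, spec in self.clinical_proportions.items():
            for group in ("EOCRC", "LOCRC"):
                probs = np.asarray(spec[group], dtype=float)
                if len(probs) != len(spec["categories"]):
                    raise ValidationError(
                        f"clinical_proportions[{cov!r}][{group!r}] length mismatch"
                    )
                if abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
                    raise ValidationError(
                        f"clinical_proportions[{cov!r}][{group!r}] must be a "
                        "probability vector summing to 1"
                    )


@dataclass
class SimulatedTruth:
    """Ground truth behind a simulated dataset.

    ``features`` has one row per feature with its true per-group effects
    (log2 tissue effects for expression; signed beta deltas and DML flags
    for methylation) plus set membership / region class.  ``gene_sets``
    holds the set memberships usable as a GMT collection.
    """

    features: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def annotation(self) -> FeatureAnnotation:
        cols = {"feature_id": self.features["feature_id"]}
        cols["gene_symbol"] = self.features.get(
            "gene_symbol", pd.Series([""] * len(self.features))
        )
        cols["region_class"] = self.features.get(
            "region_class", pd.Series(["na"] * len(self.features))
        )
        return FeatureAnnotation(pd.DataFrame(cols))

    def gene_set_collection(self) -> GeneSetCollection:
        return GeneSetCollection(dict(self.gene_sets))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named sub-stream: stable under addition of other generators."""
    digest = hashlib.sha256(stream.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(config.seed) % (2 ** 31), key])


def _make_sheet(config: SimulationConfig, rng: np.random.Generator | None = None
                ) -> pd.DataFrame:
    rows = []
    for group in ("EOCRC", "LOCRC"):
        prefix = "E" if group == "EOCRC" else "L"
        for i in range(config.n_persons_per_group[group]):
            pid = f"{prefix}{i + 1:03d}"
            for tissue, tag in (("tumor", "T"), ("normal", "N")):
                rows.append(
                    {
                        "sample_id": f"{pid}-{tag}",
                        "person_id": pid,
                        "tissue": tissue,
                        "onset_group": group,
                    }
                )
    df = pd.DataFrame(rows)
    if config.drop_normal_fraction > 0 and rng is not None:
        normals = df.index[df["tissue"] == "normal"].to_numpy()
        n_drop = int(round(config.drop_normal_fraction * len(normals)))
        drop = rng.choice(normals, size=n_drop, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)
    return df


def _feature_truth_expression(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    n_set_genes = config.n_gene_sets * config.set_size
    n_set_features = n_set_genes * config.probes_per_gene
    if n_set_features > config.n_features:
        raise ValidationError(
            "n_features too small for the requested gene sets"
        )
    records, gene_sets = [], {}
    for s in range(config.n_gene_sets):
        set_name = f"SET{s + 1:02d}"
        members = []
        for g in range(config.set_size):
            symbol = f"{set_name}G{g + 1:02d}"
            members.append(symbol)
            for pr in range(config.probes_per_gene):
                records.append(
                    {
                        "feature_id": f"{symbol}_p{pr + 1}",
                        "gene_symbol": symbol,
                        "set_name": set_name,
                        "effect_eocrc": config.tissue_effect_log2,
                        "effect_locrc": config.tissue_effect_log2
                        + config.interaction_effect_log2,
                    }
                )
        gene_sets[set_name] = members
    for b in range(config.n_features - n_set_features):
        symbol = f"BG{b + 1:05d}"
        records.append(
            {
                "feature_id": f"{symbol}_p1",
                "gene_symbol": symbol,
                "set_name": "",
                "effect_eocrc": 0.0,
                "effect_locrc": 0.0,
            }
        )
    truth = pd.DataFrame(records)
    truth["region_class"] = "na"
    return truth, gene_sets


def simulate_expression(config: SimulationConfig
                        ) -> tuple[OmicsMatrix, SampleSheet, SimulatedTruth]:
    """Simulate a paired log2 expression matrix with gene-set structure.

    Tumor samples of set-member features carry the configured tissue effect,
    plus the interaction effect when the person is late-onset; background
    features are null.  Person effects are Normal(0, sigma_person^2) shared
    by a person's two samples; residual noise is Normal(0, sigma_error^2).
    Deterministic under a fixed seed.
    """
    config.validate()
    rng = _rng(config, "expression")
    sheet_df = _make_sheet(config, rng)
    truth_df, gene_sets = _feature_truth_expression(config)

    samples = sheet_df["sample_id"].to_numpy()
    persons = sheet_df["person_id"].to_numpy()
    is_tumor = (sheet_df["tissue"] == "tumor").to_numpy()
    is_locrc = (sheet_df["onset_group"] == "LOCRC").to_numpy()

    unique_persons = pd.unique(persons)
    person_effects = dict(
        zip(unique_persons,
            rng.normal(0.0, config.sigma_person, size=len(unique_persons)))
    )
    pe = np.array([person_effects[p] for p in persons])

    eff_e = truth_df["effect_eocrc"].to_numpy()[:, None]
    eff_l = truth_df["effect_locrc"].to_numpy()[:, None]
    effect = np.where(is_locrc[None, :], eff_l, eff_e) * is_tumor[None, :]
    noise = rng.normal(0.0, config.sigma_error,
                       size=(len(truth_df), len(samples)))
    values = config.mu_log2 + pe[None, :] + effect + noise
    matrix = OmicsMatrix(
        pd.DataFrame(values, index=truth_df["feature_id"].to_numpy(),
                     columns=samples),
        "expression_log2",
    )
    return matrix, SampleSheet(sheet_df), SimulatedTruth(truth_df, gene_sets)


def simulate_methylation(config: SimulationConfig
                         ) -> tuple[OmicsMatrix, SampleSheet, SimulatedTruth]:
    """Simulate a paired beta-value matrix with designated DML.

    Loci are assigned region classes (a configurable deep-sea fraction;
    island/shore/shelf in chip proportions).  Among non-deep-sea loci,
    designated DML receive a tumor-normal beta delta: common DML in both
    onset groups (alternating hyper/hypo at ``beta_delta``), group-specific
    DML at ``beta_delta_specific`` in one group only.  Noise and person
    effects act on the logit scale; back-transformed values are clipped to
    [0.001, 0.999].
    """
    config.validate()
    rng = _rng(config, "methylation")
    sheet_df = _make_sheet(config, rng)
    n = config.n_features

    u = rng.uniform(size=n)
    region = np.empty(n, dtype=object)
    deep = u < config.deep_sea_fraction
    region[deep] = "deep_sea"
    iss_choice = rng.choice(["island", "shore", "shelf"], size=n, p=_ISS)
    region[~deep] = iss_choice[~deep]

    locus_ids = np.array([f"cg{i:08d}" for i in range(n)])
    baseline = rng.uniform(*config.beta_baseline_range, size=n)

    candidates = np.flatnonzero(~deep)
    rng.shuffle(candidates)
    n_common = int(round(config.frac_dml_common * n))
    n_eo = int(round(config.frac_dml_eocrc_specific * n))
    n_lo = int(round(config.frac_dml_locrc_specific * n))
    if n_common + n_eo + n_lo > len(candidates):
        raise ValidationError("DML fractions exceed available non-deep-sea loci")
    common = candidates[:n_common]
    eo_only = candidates[n_common:n_common + n_eo]
    lo_only = candidates[n_common + n_eo:n_common + n_eo + n_lo]

    delta_e = np.zeros(n)
    delta_l = np.zeros(n)
    signs_common = np.where(np.arange(n_common) % 2 == 0, 1.0, -1.0)
    delta_e[common] = signs_common * config.beta_delta
    delta_l[common] = signs_common * config.beta_delta
    delta_e[eo_only] = np.where(np.arange(n_eo) % 2 == 0, 1.0, -1.0) \
        * config.beta_delta_specific
    delta_l[lo_only] = np.where(np.arange(n_lo) % 2 == 0, 1.0, -1.0) \
        * config.beta_delta_specific

    for name, arr in (("common/base", baseline[common] + delta_e[common]),
                      ("eocrc", baseline[eo_only] + delta_e[eo_only]),
                      ("locrc", baseline[lo_only] + delta_l[lo_only])):
        if arr.size and ((arr < 0).any() or (arr > 1).any()):
            raise ValidationError(
                f"expected tumor beta outside [0, 1] for {name} loci"
            )

    samples = sheet_df["sample_id"].to_numpy()
    persons = sheet_df["person_id"].to_numpy()
    is_tumor = (sheet_df["tissue"] == "tumor").to_numpy()
    is_locrc = (sheet_df["onset_group"] == "LOCRC").to_numpy()

    unique_persons = pd.unique(persons)
    person_effects = dict(
        zip(unique_persons,
            rng.normal(0.0, config.sigma_person_logit,
                       size=len(unique_persons)))
    )
    pe = np.array([person_effects[p] for p in persons])

    delta = np.where(is_locrc[None, :], delta_l[:, None], delta_e[:, None])
    mean_beta = baseline[:, None] + delta * is_tumor[None, :]
    mean_beta = np.clip(mean_beta, 1e-6, 1 - 1e-6)
    z = logit(mean_beta) + pe[None, :] + rng.normal(
        0.0, config.sigma_error_logit, size=(n, len(samples))
    )
    beta = np.clip(expit(z), 0.001, 0.999)

    truth_df = pd.DataFrame(
        {
            "feature_id": locus_ids,
            "gene_symbol": "",
            "region_class": region.astype(str),
            "baseline_beta": baseline,
            "delta_eocrc": delta_e,
            "delta_locrc": delta_l,
            "is_dml_eocrc": delta_e != 0,
            "is_dml_locrc": delta_l != 0,
        }
    )
    matrix = OmicsMatrix(
        pd.DataFrame(beta, index=locus_ids, columns=samples),
        "methylation_beta",
    )
    return matrix, SampleSheet(sheet_df), SimulatedTruth(truth_df)


def simulate_clinical(config: SimulationConfig,
                      exact_counts: dict | None = None) -> SampleSheet:
    """Simulate a sample sheet with per-person clinical covariates.

    Categories are drawn per person from the onset-group-specific
    distributions in ``config.clinical_proportions``.  With
    ``exact_counts`` — a mapping ``covariate -> {group -> {category: n}}``
    — the requested cross-tabulation is reproduced exactly (counts must sum
    to the group size); remaining covariates stay probabilistic.
    """
    config.validate()
    rng = _rng(config, "clinical")
    sheet_df = _make_sheet(config)
    persons = sheet_df.drop_duplicates("person_id")[["person_id", "onset_group"]]

    assignments: dict[str, dict[str, str]] = {}
    for cov, spec in config.clinical_proportions.items():
        categories = list(spec["categories"])
        per_person: dict[str, str] = {}
        for group, sub in persons.groupby("onset_group"):
            ids = list(sub["person_id"])
            if exact_counts and cov in exact_counts:
                counts = exact_counts[cov][group]
                if sum(counts.values()) != len(ids):
                    raise ValidationError(
                        f"exact counts for {cov!r}/{group!r} sum to "
                        f"{sum(counts.values())}, expected {len(ids)}"
                    )
                labels = [c for c, k in counts.items() for _ in range(k)]
                # decorrelate from other covariates; group counts stay exact
                labels = list(rng.permutation(labels))
            else:
                labels = list(
                    rng.choice(categories, size=len(ids),
                               p=np.asarray(spec[group], dtype=float))
                )
            per_person.update(dict(zip(ids, labels)))
        assignments[cov] = per_person

    for cov, mapping in assignments.items():
        sheet_df[cov] = sheet_df["person_id"].map(mapping)
    return SampleSheet(sheet_df)
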
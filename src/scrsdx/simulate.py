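"""Synthetic PBMC Raman cohorts.

Generates subjects, cells, raw acquisitions and clinical scores with the
statistical structure the downstream analysis assumes, so every pipeline
stage is testable without any external download.

The default configuration emulates a 98-subject study: 16 healthy controls
(HC), 61 ME/CFS patients split by severity (25 mild, 15 moderate, 21
severe) and 21 multiple-sclerosis (MS) disease controls; ~30 cells per
subject with 5-10 acquisitions per cell on the canonical 319-3401 cm^-1 /
1019-channel grid.

Each acquisition is a sum of Lorentzian peaks (FWHM 10 cm^-1), scaled by a
per-cell latent concentration (log-normal, sigma 0.15, shared by the
cell's acquisitions) and by group-specific multiplicative effects at eight
biomarker bands, sitting on a random positive 5th-order polynomial
fluorescence baseline, with additive Gaussian noise, a per-acquisition
multiplicative scale and occasional single-channel cosmic-ray spikes.

Clinical scores are assigned by stratified inverse-CDF sampling so that the
configured group medians are realized *exactly* at the default sizes:
Fatigue Severity Scale medians 59 (ME/CFS, range 44-63), 54 (MS, 16-63)
and 17 (HC, 11-37).  The symptom table holds 63 ordinal 0-3 variables with
a severity gradient HC < mild < moderate < severe and MCAR missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import RawSpectrum, SpectralAxis, make_canonical_axis

__all__ = [
    "GROUPS",
    "ME_GROUPS",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_EFFECT_TABLE",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "default_config",
    "generate_cohort",
    "synth_cell_spectra",
    "assign_clinical_scores",
    "synth_symptom_table",
    "make_mixture_classes",
]

GROUPS = ("HC", "MildME", "ModME", "SevME", "MS")
ME_GROUPS = ("MildME", "ModME", "SevME")

DEFAULT_GROUP_SIZES = {"HC": 16, "MildME": 25, "ModME": 15, "SevME": 21, "MS": 21}

# Peak library: (center cm^-1, amplitude a.u., band name or None for a
# generic cellular band).  Named bands carry group effects; the generic
# protein/lipid/nucleic-acid bands are identical across groups so that
# classifiers must find the informative channels.
PEAK_LIBRARY: tuple[tuple[float, float, str | None], ...] = (
    (405.0, 0.35, "glucose"),
    (485.0, 0.35, "glycogen"),
    (617.0, 0.40, "cholesterol_ce"),
    (758.0, 0.50, "tryptophan"),
    (860.0, 0.45, "tyrosine"),
    (1003.0, 0.60, "phenylalanine"),
    (1114.0, 0.40, "glycerol"),
    (3010.0, 0.50, "unsaturated_fa"),
    # generic cellular bands
    (640.0, 0.30, None),
    (785.0, 0.55, None),   # DNA/RNA ring breathing
    (830.0, 0.30, None),
    (880.0, 0.35, None),
    (935.0, 0.30, None),
    (1065.0, 0.35, None),
    (1250.0, 0.55, None),  # amide III
    (1320.0, 0.45, None),
    (1340.0, 0.45, None),
    (1450.0, 0.70, None),  # CH2 deformation
    (1550.0, 0.35, None),
    (1580.0, 0.40, None),
    (1660.0, 0.80, None),  # amide I
    (1745.0, 0.30, None),  # ester C=O
    (2850.0, 0.90, None),  # CH2 symmetric stretch
    (2885.0, 1.00, None),
    (2930.0, 1.20, None),  # CH3 stretch
    (2970.0, 1.00, None),
    (3060.0, 0.40, None),
)

# Multiplicative concentration effects relative to HC (=1.0); directions
# follow the biomarker panel: tryptophan/tyrosine/glycerol elevated in all
# disease groups; phenylalanine and unsaturated fatty acids elevated in
# mild ME and MS but reduced in moderate/severe ME; cholesterol reduced
# everywhere (most in MS); glycogen reduced in mild/severe ME and MS;
# glucose reduced in all disease groups with MS lowest.
DEFAULT_EFFECT_TABLE: dict[tuple[str, str], float] = {
    ("tryptophan", "MildME"): 1.20, ("tryptophan", "ModME"): 1.25,
    ("tryptophan", "SevME"): 1.30, ("tryptophan", "MS"): 1.25,
    ("tyrosine", "MildME"): 1.20, ("tyrosine", "ModME"): 1.25,
    ("tyrosine", "SevME"): 1.30, ("tyrosine", "MS"): 1.25,
    ("phenylalanine", "MildME"): 1.20, ("phenylalanine", "ModME"): 0.75,
    ("phenylalanine", "SevME"): 0.70, ("phenylalanine", "MS"): 1.20,
    ("glycerol", "MildME"): 1.25, ("glycerol", "ModME"): 1.25,
    ("glycerol", "SevME"): 1.25, ("glycerol", "MS"): 1.25,
    ("unsaturated_fa", "MildME"): 1.20, ("unsaturated_fa", "ModME"): 0.80,
    ("unsaturated_fa", "SevME"): 0.80, ("unsaturated_fa", "MS"): 1.20,
    ("cholesterol_ce", "MildME"): 0.85, ("cholesterol_ce", "ModME"): 0.85,
    ("cholesterol_ce", "SevME"): 0.80, ("cholesterol_ce", "MS"): 0.70,
    ("glycogen", "MildME"): 0.80, ("glycogen", "ModME"): 1.00,
    ("glycogen", "SevME"): 0.80, ("glycogen", "MS"): 0.80,
    ("glucose", "MildME"): 0.80, ("glucose", "ModME"): 0.80,
    ("glucose", "SevME"): 0.75, ("glucose", "MS"): 0.70,
}

# Fatigue Severity Scale (9-63) targets: (median, low, high), the ME/CFS
# entry applies to the pooled mild+moderate+severe patients.
DEFAULT_FSS_TARGETS = {"ME": (59, 44, 63), "MS": (54, 16, 63), "HC": (17, 11, 37)}

# SF-36 Physical Function (0-100): mild ME is defined by PF > 25,
# moderate/severe by PF < 25 (severe additionally house- or bed-bound).
DEFAULT_PF_RANGES = {
    "HC": (80, 100), "MildME": (30, 75), "ModME": (5, 24), "SevME": (0, 15),
    "MS": (25, 80),
}

# Symptom propensity multipliers (probability scale of the per-variable
# ordinal intensity); gradient HC << mild < MS < moderate < severe.
DEFAULT_SYMPTOM_MULTIPLIERS = {
    "HC": 0.08, "MildME": 0.45, "ModME": 0.60, "SevME": 0.80, "MS": 0.50,
}

_MED_PROPENSITY = {
    "opiate": {"HC": 0.02, "MildME": 0.15, "ModME": 0.25, "SevME": 0.35, "MS": 0.20},
    "tricyclic_or_mirtazapine": {
        "HC": 0.02, "MildME": 0.20, "ModME": 0.25, "SevME": 0.30, "MS": 0.15
    },
}


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate the study cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    cells_per_subject: int = 30
    acquisitions_per_cell: tuple[int, int] = (5, 10)
    axis_spec: tuple[float, float, int] = (319.0, 3401.0, 1019)
    effect_table: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_TABLE))
    baseline_order: int = 5
    baseline_amplitude: tuple[float, float] = (0.0, 5.0)  # x mean peak height
    noise_sd: float = 0.02                  # additive, a.u.
    scale_sd: float = 0.05                  # per-acquisition log-normal sigma
    cell_sigma: float = 0.15                # per-cell log-normal concentration sigma
    spike_probability: float = 0.10         # per acquisition
    spike_amplitude: tuple[float, float] = (50.0, 140.0)  # x robust noise scale
    peak_fwhm: float = 10.0                 # cm^-1
    fss_targets: dict = field(default_factory=lambda: dict(DEFAULT_FSS_TARGETS))
    pf_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PF_RANGES))
    symptom_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_MULTIPLIERS)
    )
    n_symptoms: int = 63
    me_specific_fraction: float = 1 / 3   # share of variables tilted against MS
    ms_symptom_tilt: float = 0.5          # MS multiplier factor on those variables
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if self.group_sizes[g] < 0:
                raise ValueError("group sizes must be >= 0")
        if self.cells_per_subject < 0 or self.acquisitions_per_cell[0] < 1:
            raise ValueError("cell/acquisition counts must be positive")
        if self.acquisitions_per_cell[0] > self.acquisitions_per_cell[1]:
            raise ValueError("acquisitions_per_cell range inverted")
        start, end, n = self.axis_spec
        if end <= start or n < 2:
            raise ValueError("invalid axis_spec")
        for (band, group), f in self.effect_table.items():
            if f <= 0:
                raise ValueError(f"effect factor for {(band, group)} must be > 0")
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} in effect table")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must be in [0, 1]")

    def axis(self) -> SpectralAxis:
        return make_canonical_axis(*self.axis_spec)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    return replace(CohortConfig(seed=seed), **overrides)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str = "F"
    age: float = 45.0
    bmi: float = 25.0
    disease_duration: float = 0.0
    med_opiate: bool = False
    med_tricyclic_or_mirtazapine: bool = False
    fss: int = 9
    sf36_pf: int = 100
    cell_ids: list = field(default_factory=list)

    @property
    def severity(self) -> str:
        return {"MildME": "mild", "ModME": "moderate", "SevME": "severe"}.get(
            self.group, "none"
        )

    @property
    def is_me(self) -> bool:
        return self.group in ME_GROUPS


@dataclass
class Cohort:
    subjects: list
    spectra: list
    symptom_table: "object"          # clinical.SymptomTable or None
    config: CohortConfig

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "severity": s.severity,
                "sex": s.sex,
                "age": s.age,
                "bmi": s.bmi,
                "disease_duration": s.disease_duration,
                "med_opiate": s.med_opiate,
                "med_tricyclic_or_mirtazapine": s.med_tricyclic_or_mirtazapine,
                "fss": s.fss,
                "sf36_pf": s.sf36_pf,
            }
            for s in self.subjects
        ]
        cols = [
            "subject_id", "group", "severity", "sex", "age", "bmi",
            "disease_duration", "med_opiate", "med_tricyclic_or_mirtazapine",
            "fss", "sf36_pf",
        ]
        return pd.DataFrame(rows, columns=cols)

    def groups_by_subject(self) -> dict:
        return {s.subject_id: s.group for s in self.subjects}


# --------------------------------------------------------------------------
# clinical scores

def _stratified_scores(n: int, median: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Integer scores in [lo, hi] whose sample median is exactly ``median``.

    Mid-quantile positions are pushed through a piecewise-linear inverse CDF
    (uniform on [lo, median] below p=0.5, uniform on [median, hi] above),
    rounded, and the middle order statistic(s) pinned to the median.
    """
    if not lo <= median <= hi:
        raise ValueError("median outside range")
    if n == 0:
        return np.array([], dtype=int)
    if lo == hi:
        return np.full(n, int(lo))
    q = (np.arange(n) + 0.5) / n
    x = np.where(q <= 0.5, lo + 2 * q * (median - lo), median + (2 * q - 1) * (hi - median))
    s = np.sort(np.clip(np.rint(x), lo, hi).astype(int))
    if n % 2 == 1:
        s[n // 2] = int(round(median))
    else:
        s[n // 2 - 1] = s[n // 2] = int(round(median))
    return s


def assign_clinical_scores(subjects: list, config: CohortConfig,
                           rng: np.random.Generator) -> list:
    """Assign FSS and SF-36 PF scores in place; exact group medians.

    FSS strata are the three fatigue categories (pooled ME/CFS, MS, HC).
    Within ME/CFS the sorted scores are distributed mild < moderate <
    severe (shuffled inside each severity block) so that fatigue tracks
    severity while the pooled median stays pinned.
    """
    by_cat = {"ME": [s for s in subjects if s.is_me],
              "MS": [s for s in subjects if s.group == "MS"],
              "HC": [s for s in subjects if s.group == "HC"]}
    for cat, members in by_cat.items():
        med, lo, hi = config.fss_targets[cat]
        scores = _stratified_scores(len(members), med, lo, hi, rng)
        if cat == "ME":
            ordered = (
                [s for s in members if s.group == "MildME"]
                + [s for s in members if s.group == "ModME"]
                + [s for s in members if s.group == "SevME"]
            )
            pos = 0
            for grp in ME_GROUPS:
                block = [s for s in ordered if s.group == grp]
                vals = scores[pos: pos + len(block)]
                vals = rng.permutation(vals)
                for s, v in zip(block, vals):
                    s.fss = int(v)
                pos += len(block)
        else:
            vals = rng.permutation(scores)
            for s, v in zip(members, vals):
                s.fss = int(v)
    for grp in GROUPS:
        members = [s for s in subjects if s.group == grp]
        lo, hi = config.pf_ranges[grp]
        med = (lo + hi) / 2
        vals = rng.permutation(_stratified_scores(len(members), med, lo, hi, rng))
        for s, v in zip(members, vals):
            s.sf36_pf = int(v)
    return subjects


# --------------------------------------------------------------------------
# spectra

def _lorentzian(w: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma**2 / ((w - center) ** 2 + gamma**2)


def _group_signal(axis: SpectralAxis, group: str, config: CohortConfig) -> np.ndarray:
    w = axis.wavenumbers
    y = np.zeros_like(w)
    for center, amp, band in PEAK_LIBRARY:
        if not (w[0] <= center <= w[-1]):
            raise ValueError(f"band center {center} cm^-1 outside axis")
        f = config.effect_table.get((band, group), 1.0) if band else 1.0
        y += amp * f * _lorentzian(w, center, config.peak_fwhm)
    return y


def _mean_peak_height(config: CohortConfig) -> float:
    return float(np.mean([amp for _, amp, _ in PEAK_LIBRARY]))


def _random_baseline(w: np.ndarray, config: CohortConfig,
                     rng: np.random.Generator) -> np.ndarray:
    t = (w - w[0]) / (w[-1] - w[0])
    coeff = rng.uniform(0.05, 1.0, size=config.baseline_order + 1)
    poly = np.polyval(coeff, t)
    poly /= poly.max()
    lo, hi = config.baseline_amplitude
    return rng.uniform(lo, hi) * _mean_peak_height(config) * poly


def synth_cell_spectra(subject: SubjectRecord, config: CohortConfig,
                       rng: np.random.Generator,
                       spike_rng: np.random.Generator | None = None,
                       signal: np.ndarray | None = None,
                       axis: SpectralAxis | None = None) -> list[RawSpectrum]:
    """All acquisitions for all cells of one subject.

    Cosmic-ray spikes are drawn from ``spike_rng`` (a dedicated stream) so
    that toggling the spike probability leaves every other random draw --
    hence the spike-free twin spectrum -- unchanged.
    """
    axis = axis or config.axis()
    if signal is None:
        signal = _group_signal(axis, subject.group, config)
    if spike_rng is None:
        spike_rng = np.random.default_rng(rng.integers(2**31))
    lo_acq, hi_acq = config.acquisitions_per_cell
    spectra: list[RawSpectrum] = []
    noise_scale_ref = max(config.noise_sd, 1e-12)
    subject.cell_ids = []
    for ci in range(config.cells_per_subject):
        cell_id = f"{subject.subject_id}_c{ci:03d}"
        subject.cell_ids.append(cell_id)
        conc = float(rng.lognormal(mean=0.0, sigma=config.cell_sigma))
        n_acq = int(rng.integers(lo_acq, hi_acq + 1))
        for ai in range(n_acq):
            scale = float(rng.lognormal(mean=0.0, sigma=config.scale_sd))
            y = scale * conc * signal
            y = y + _random_baseline(axis.wavenumbers, config, rng)
            y = y + rng.normal(0.0, config.noise_sd, size=axis.n_channels)
            if spike_rng.uniform() < config.spike_probability:
                chan = int(spike_rng.integers(axis.n_channels))
                amp = spike_rng.uniform(*config.spike_amplitude)
                y = y.copy()
                y[chan] += amp * noise_scale_ref
            spectra.append(RawSpectrum(axis, y, subject.subject_id, cell_id, f"a{ai}"))
    return spectra


# --------------------------------------------------------------------------
# symptom table

def synth_symptom_table(subjects: list, config: CohortConfig,
                        rng: np.random.Generator):
    """Ordinal 0-3 symptom table (subjects x variables) with MCAR missingness.

    Entry ~ Binomial(3, p) with p = per-variable base intensity x group
    multiplier; a configurable fraction of the variables is "ME-typical"
    (their MS multiplier is tilted down) so that the severe-ME vs MS fold
    selection has something to find.  Setting the tilt to 1 and equal
    multipliers makes the propensities identical across groups.
    """
    from .clinical import SymptomTable  # local import to avoid a cycle

    if not subjects:
        raise ValueError("cohort is empty")
    n_var = config.n_symptoms
    names = [f"symptom_{i:02d}" for i in range(1, n_var + 1)]
    base = rng.uniform(0.25, 0.95, size=n_var)
    me_typical = rng.uniform(size=n_var) < config.me_specific_fraction
    rows = {}
    for s in subjects:
        mult = np.full(n_var, config.symptom_multipliers[s.group])
        if s.group == "MS":
            mult = np.where(me_typical, mult * config.ms_symptom_tilt, mult)
        p = np.clip(base * mult, 0.0, 0.97)
        vals = rng.binomial(3, p).astype(float)
        miss = rng.uniform(size=n_var) < config.missing_rate
        vals[miss] = np.nan
        rows[s.subject_id] = vals
    data = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    groups = pd.Series({s.subject_id: s.group for s in subjects}, name="group")
    return SymptomTable(data=data, groups=groups.loc[data.index])


# --------------------------------------------------------------------------
# cohort assembly

def generate_cohort(config: CohortConfig | None = None,
                    include_spectra: bool = True) -> Cohort:
    """Deterministic function of ``config.seed``.

    Independent child RNG streams are spawned for clinical scores, symptom
    table, covariates and per-subject spectra, so e.g. the clinical scores
    do not depend on whether spectra are generated.
    """
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_clin, ss_sym, ss_cov, ss_spec = ss.spawn(4)

    subjects: list[SubjectRecord] = []
    idx = 1
    for grp in GROUPS:
        for _ in range(int(config.group_sizes.get(grp, 0))):
            subjects.append(SubjectRecord(subject_id=f"S{idx:03d}", group=grp))
            idx += 1

    cov_rng = np.random.default_rng(ss_cov)
    for s in subjects:
        p_female = 0.5 if s.group == "HC" else 0.7
        s.sex = "F" if cov_rng.uniform() < p_female else "M"
        s.age = float(np.clip(cov_rng.normal(45, 12), 18, 70).round(1))
        s.bmi = float(np.clip(cov_rng.normal(25, 4), 16, 40).round(1))
        s.disease_duration = (
            0.0 if s.group == "HC" else round(float(cov_rng.uniform(0.5, 20)), 1)
        )
        s.med_opiate = bool(cov_rng.uniform() < _MED_PROPENSITY["opiate"][s.group])
        s.med_tricyclic_or_mirtazapine = bool(
            cov_rng.uniform() < _MED_PROPENSITY["tricyclic_or_mirtazapine"][s.group]
        )

    assign_clinical_scores(subjects, config, np.random.default_rng(ss_clin))

    spectra: list[RawSpectrum] = []
    if include_spectra and subjects and config.cells_per_subject > 0:
        axis = config.axis()
        signals = {g: _group_signal(axis, g, config) for g in GROUPS}
        child = ss_spec.spawn(2 * len(subjects))
        for i, s in enumerate(subjects):
            rng = np.random.default_rng(child[2 * i])
            spike_rng = np.random.default_rng(child[2 * i + 1])
            spectra.extend(
                synth_cell_spectra(s, config, rng, spike_rng,
                                   signal=signals[s.group], axis=axis)
            )

    symptom_table = (
        synth_symptom_table(subjects, config, np.random.default_rng(ss_sym))
        if subjects else None
    )
    return Cohort(subjects=subjects, spectra=spectra,
                  symptom_table=symptom_table, config=config)


# --------------------------------------------------------------------------
# feature-space classifier test-bed

def make_mixture_classes(n_classes: int = 5, n_per_class: int = 80,
                         n_block: int = 4, linear_sd: float = 1.0,
                         cluster_spread: float = 5.0, noise_sd: float = 2.5,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Multi-class data whose signal is split across model families.

    Three feature blocks of ``n_block`` features each carry complementary
    class signal: (i) weak random mean shifts, which linear classifiers
    exploit; (ii) mirrored Gaussian cluster pairs (+/- the same center, so
    class means vanish), visible only to mixture/flexible models; (iii) a
    per-class variance signature (classes differ in spread, not location),
    invisible to any shared-covariance model but usable by kernel and tree
    methods.  No single base learner is well-specified for all three
    blocks, which is the regime in which stacking heterogeneous
    classifiers outperforms each of them.
    """
    rng = np.random.default_rng(seed)
    lin_means = rng.normal(0.0, linear_sd, size=(n_classes, n_block))
    scales = 0.6 + 0.45 * rng.permutation(n_classes)
    X, y = [], []
    for c in range(n_classes):
        center = rng.normal(0.0, cluster_spread, size=n_block)
        for i in range(n_per_class):
            lin = lin_means[c] + rng.normal(0.0, noise_sd, size=n_block)
            mu = center if i % 2 == 0 else -center
            nonlin = mu + rng.normal(0.0, noise_sd, size=n_block)
            var = rng.normal(0.0, scales[c], size=n_block)
            X.append(np.concatenate([lin, nonlin, var]))
            y.append(c)
    X = np.asarray(X)
    y = np.asarray(y)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
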
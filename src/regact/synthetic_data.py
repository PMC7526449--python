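"""Multi-cohort synthetic expression and clinical data with known truth.

The generator emulates the statistical structure of a multi-cohort skin
gene-expression study of systemic sclerosis:

* four intrinsic subsets (fibroproliferative, inflammatory, limited,
  normal-like), each with planted subset-specific regulators whose target
  genes are shifted in that subset's samples (TF targets up, miRNA targets
  down, by ``delta`` log2 units over Gaussian noise ``sigma``);
* continuous "driver" regulators whose per-sample activation dose shifts
  their targets and feeds the MRSS model, so activity correlates with skin
  severity within every subset;
* a severe double-positive subgroup: the two severe-pair drivers define
  sign quadrants, and samples in the double-positive quadrant receive an
  MRSS shift, a higher ILD probability, and a declining FVC trajectory;
* two expression dialects (two-channel log ratios centred at zero, or
  positive single-channel log2 intensities).

Everything is reproducible from the config seed, and the emitted ground
truth records what was planted so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    SINGLE_CHANNEL,
    TWO_CHANNEL,
    ClinicalTable,
    ExpressionMatrix,
    RegulatorSet,
    classify_regulator,
    extract_symbol,
)

SUBSET_ORDER = ("fibroproliferative", "inflammatory", "limited", "normal_like")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_regulators: int = 100
    targets_per_regulator: int = 30
    mirna_fraction: float = 0.2
    subsets: tuple[str, ...] = SUBSET_ORDER
    samples_per_subset: int = 15
    #: subset -> names of regulators active only there
    planted: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: regulators with continuous per-sample activation feeding MRSS
    mrss_drivers: tuple[str, ...] = ()
    severe_pair: tuple[str, str] | None = None
    delta: float = 2.0  # expression shift of target genes, log2 units
    sigma: float = 1.0  # per-gene Gaussian noise, log2 units
    mrss_base: float = 14.0
    mrss_coefficient: float = 5.0  # MRSS units per driver dose sd
    mrss_noise_sd: float = 4.0
    mrss_noise_floor: float = 0.5
    severe_shift: float = 8.0  # extra MRSS in the double-positive quadrant
    ild_prob_double_positive: float = 0.5
    ild_prob_background: float = 0.2
    fvc_baseline_mean: float = 95.0
    fvc_baseline_sd: float = 10.0
    fvc_slope_group1: float = -0.25  # %predicted per month
    fvc_slope_other: float = 0.0
    fvc_followup_months: float = 42.0
    fvc_noise_sd: float = 2.0
    dcssc_prob_double_positive: float = 0.6
    dcssc_prob_background: float = 0.35
    dialect: str = TWO_CHANNEL
    seed: int = 0

    def regulator_names(self) -> list[str]:
        n_mirna = int(round(self.n_regulators * self.mirna_fraction))
        n_tf = self.n_regulators - n_mirna
        return [f"REG{i:03d}_01" for i in range(n_tf)] + [
            f"MIR{i:03d}_5P" for i in range(n_mirna)
        ]

    def all_drivers(self) -> tuple[str, ...]:
        drivers = list(self.mrss_drivers)
        if self.severe_pair:
            for r in self.severe_pair:
                if r not in drivers:
                    drivers.append(r)
        return tuple(drivers)

    def validate(self) -> None:
        if self.targets_per_regulator >= self.n_genes:
            raise SimulationError("targets_per_regulator must be < n_genes")
        if self.n_regulators >= self.n_genes:
            raise SimulationError("n_regulators must be < n_genes")
        names = set(self.regulator_names())
        for subset, regs in self.planted.items():
            if subset not in self.subsets:
                raise SimulationError(f"planted subset {subset!r} not simulated")
            missing = set(regs) - names
            if missing:
                raise SimulationError(
                    f"planted regulator(s) do not exist: {sorted(missing)}"
                )
        missing = set(self.all_drivers()) - names
        if missing:
            raise SimulationError(f"driver(s) do not exist: {sorted(missing)}")
        for p in (
            self.ild_prob_double_positive,
            self.ild_prob_background,
            self.dcssc_prob_double_positive,
            self.dcssc_prob_background,
            self.mirna_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.dialect not in (TWO_CHANNEL, SINGLE_CHANNEL):
            raise SimulationError(f"unknown dialect {self.dialect!r}")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-shaped defaults: 10 planted intrinsic regulators (3/3/2/2
    across the four subsets) and a severe driver pair feeding MRSS."""
    cfg = SimulationConfig(seed=seed, **overrides)
    names = cfg.regulator_names()
    if len(names) < 12:
        raise SimulationError("default planted structure needs >=12 regulators")
    planted = {
        cfg.subsets[0]: tuple(names[0:3]),
        cfg.subsets[1]: tuple(names[3:6]),
        cfg.subsets[2]: tuple(names[6:8]),
        cfg.subsets[3]: tuple(names[8:10]),
    }
    pair = (names[10], names[11])
    return replace(cfg, planted=planted, mrss_drivers=pair, severe_pair=pair)


@dataclass
class GroundTruth:
    planted: dict[str, tuple[str, ...]]
    mrss_drivers: tuple[str, ...]
    severe_pair: tuple[str, str] | None
    sample_subset: dict[str, str]
    sample_quadrant: dict[str, int]  # truth quadrant of the severe pair
    driver_dose: pd.DataFrame  # drivers x samples
    fvc_slope: dict[str, float]  # patient -> %predicted per month

    def planted_regulators(self) -> set[str]:
        return {r for regs in self.planted.values() for r in regs}


def _gene_universe(cfg: SimulationConfig) -> list[str]:
    """Gene symbols: regulators are themselves expressed genes (so target
    lists can contain other regulators and networks are non-trivial),
    padded with anonymous fillers up to ``n_genes``."""
    symbols = []
    for name in cfg.regulator_names():
        sym = extract_symbol(name) or name
        if sym not in symbols:
            symbols.append(sym)
    fillers = [f"G{i:04d}" for i in range(cfg.n_genes - len(symbols))]
    return symbols + fillers


def _draw_sets(cfg: SimulationConfig, rng: np.random.Generator) -> list[RegulatorSet]:
    """Draw target sets; planted/driver targets come from a reserved pool.

    Regulators carrying planted effects draw first and their target genes
    are withheld from the remaining regulators, so the planted ground truth
    stays identifiable: an unplanted regulator cannot inherit a subset
    effect through shared targets. Unplanted regulators still overlap each
    other freely, as motif sets do.
    """
    genes = np.array(_gene_universe(cfg), dtype=object)
    effect_regs = {r for regs in cfg.planted.values() for r in regs}
    effect_regs |= set(cfg.all_drivers())
    reserved: set[str] = set()
    sets_by_name: dict[str, RegulatorSet] = {}
    names = cfg.regulator_names()

    def make(name: str, pool: np.ndarray) -> RegulatorSet:
        if pool.size < cfg.targets_per_regulator:
            raise SimulationError(
                "gene pool too small for targets_per_regulator; "
                "increase n_genes or reduce planted regulators"
            )
        targets = rng.choice(pool, size=cfg.targets_per_regulator, replace=False)
        return RegulatorSet(
            name=name,
            regulator_class=classify_regulator(name),
            gene_symbol=extract_symbol(name) or name,
            targets=frozenset(targets.tolist()),
        )

    for name in names:
        if name in effect_regs:
            s = make(name, genes)
            reserved.update(s.targets)
            sets_by_name[name] = s
    free = np.array(sorted(set(genes.tolist()) - reserved), dtype=object)
    for name in names:
        if name not in effect_regs:
            sets_by_name[name] = make(name, free)
    return [sets_by_name[name] for name in names]


def simulate_dataset(
    cfg: SimulationConfig,
    sets: list[RegulatorSet] | None = None,
    cohort_id: str = "",
) -> tuple[ExpressionMatrix, list[RegulatorSet], ClinicalTable, GroundTruth]:
    """One cohort: expression matrix, regulator sets, clinical table, truth.

    Target sets are drawn without replacement per regulator (overlap between
    regulators is allowed, as motif sets overlap in practice); pass ``sets``
    to reuse a shared regulator universe across cohorts.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if sets is None:
        sets = _draw_sets(cfg, rng)
    by_name = {s.name: s for s in sets}

    genes = _gene_universe(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    subsets_per_sample = [
        sub for sub in cfg.subsets for _ in range(cfg.samples_per_subset)
    ]
    n_samples = len(subsets_per_sample)
    prefix = f"{cohort_id}_" if cohort_id else ""
    samples = [f"{prefix}S{i:03d}" for i in range(n_samples)]

    expr = rng.normal(0.0, cfg.sigma, size=(cfg.n_genes, n_samples))

    def shift_sign(name: str) -> float:
        # miRNAs repress their targets; an active miRNA pushes them down
        return -1.0 if by_name[name].regulator_class == "miRNA" else 1.0

    # subset-specific planted regulators: fixed shift in their own subset
    subset_arr = np.array(subsets_per_sample, dtype=object)
    for subset, regs in cfg.planted.items():
        cols = np.flatnonzero(subset_arr == subset)
        for name in regs:
            idx = [gene_pos[t] for t in by_name[name].targets]
            expr[np.ix_(idx, cols)] += cfg.delta * shift_sign(name)

    # continuous drivers: per-sample dose shifts targets and drives MRSS
    drivers = cfg.all_drivers()
    dose = rng.normal(0.0, 1.0, size=(len(drivers), n_samples))
    for d, name in enumerate(drivers):
        idx = [gene_pos[t] for t in by_name[name].targets]
        expr[idx, :] += cfg.delta * shift_sign(name) * dose[d][None, :]

    if cfg.severe_pair:
        ia = drivers.index(cfg.severe_pair[0])
        ib = drivers.index(cfg.severe_pair[1])
        a_pos, b_pos = dose[ia] > 0, dose[ib] > 0
        quadrant = np.where(a_pos, np.where(b_pos, 1, 2), np.where(b_pos, 4, 3))
    else:
        quadrant = np.full(n_samples, 3)
    double_pos = quadrant == 1

    noise_sd = max(cfg.mrss_noise_sd, cfg.mrss_noise_floor)
    mrss = (
        cfg.mrss_base
        + cfg.mrss_coefficient * dose.sum(axis=0)
        + cfg.severe_shift * double_pos
        + rng.normal(0.0, noise_sd, size=n_samples)
    )
    mrss = np.clip(np.round(mrss), 0, 51).astype(int)

    ild_p = np.where(
        double_pos, cfg.ild_prob_double_positive, cfg.ild_prob_background
    )
    ild = rng.random(n_samples) < ild_p
    dcssc_p = np.where(
        double_pos, cfg.dcssc_prob_double_positive, cfg.dcssc_prob_background
    )
    dcssc = rng.random(n_samples) < dcssc_p

    fvc_base = rng.normal(cfg.fvc_baseline_mean, cfg.fvc_baseline_sd, n_samples)
    slope = np.where(double_pos, cfg.fvc_slope_group1, cfg.fvc_slope_other)
    fvc_late = (
        fvc_base
        + slope * cfg.fvc_followup_months
        + rng.normal(0.0, cfg.fvc_noise_sd, n_samples)
    )
    duration = rng.lognormal(mean=3.3, sigma=0.8, size=n_samples)
    age = np.clip(rng.normal(45.0, 12.0, n_samples), 18, 85)
    treatment = rng.choice(
        ["none", "mmf", "mtx"], p=[0.6, 0.25, 0.15], size=n_samples
    )

    patients = [f"{prefix}P{i:03d}" for i in range(n_samples)]
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": patients,
            "mrss": mrss,
            "subset": subsets_per_sample,
            "cutaneous_subtype": np.where(dcssc, "dcSSc", "lcSSc"),
            "disease_duration_months": np.round(duration, 1),
            "age_at_diagnosis": np.round(age, 1),
            "treatment": treatment,
            "ild": [bool(v) for v in ild],
            "fvc_percent_predicted": [
                [(0.0, round(float(b), 1)), (cfg.fvc_followup_months, round(float(f), 1))]
                for b, f in zip(fvc_base, fvc_late)
            ],
            "early_stage": duration < 18,
        }
    ).set_index("sample_id")

    values = expr if cfg.dialect == TWO_CHANNEL else np.maximum(expr + 8.0, 0.05)
    em = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        dialect=cfg.dialect,
    )
    truth = GroundTruth(
        planted={k: tuple(v) for k, v in cfg.planted.items()},
        mrss_drivers=drivers,
        severe_pair=cfg.severe_pair,
        sample_subset=dict(zip(samples, subsets_per_sample)),
        sample_quadrant=dict(zip(samples, (int(q) for q in quadrant))),
        driver_dose=pd.DataFrame(dose, index=list(drivers), columns=samples),
        fvc_slope=dict(zip(patients, (float(s) for s in slope))),
    )
    return em, sets, ClinicalTable(data=clinical), truth


def simulate_multicohort(
    cfgs: list[SimulationConfig], shared_truth: bool = True
) -> list[tuple[ExpressionMatrix, list[RegulatorSet], ClinicalTable, GroundTruth]]:
    """Several cohorts, optionally over one shared regulator universe.

    With ``shared_truth`` the regulator sets and planted assignments come
    from the first config (cohorts may still differ in noise, size and
    dialect); without it every cohort is fully independent.
    """
    if len(cfgs) < 2:
        raise SimulationError("need >=2 cohort configs")
    if not shared_truth:
        return [
            simulate_dataset(cfg, cohort_id=f"C{i}") for i, cfg in enumerate(cfgs)
        ]
    first = cfgs[0]
    for cfg in cfgs[1:]:
        if (
            cfg.n_genes != first.n_genes
            or cfg.n_regulators != first.n_regulators
            or cfg.targets_per_regulator != first.targets_per_regulator
            or cfg.mirna_fraction != first.mirna_fraction
            or cfg.planted != first.planted
            or cfg.all_drivers() != first.all_drivers()
        ):
            raise SimulationError(
                "shared_truth requires matching regulator universes and truth"
            )
    first.validate()
    rng = np.random.default_rng(np.random.SeedSequence(first.seed, spawn_key=(0,)))
    sets = _draw_sets(first, rng)
    return [
        simulate_dataset(cfg, sets=sets, cohort_id=f"C{i}")
        for i, cfg in enumerate(cfgs)
    ]
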
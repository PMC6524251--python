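"""Synthetic two-arm methylation study generator.

The generators emulate the statistical structure the downstream analysis
assumes, on two arms sharing one CpG map:

* a **cohort arm** (default 25 exposed vs 54 controls) of whole-blood-like
  cell mixtures: per-sample Dirichlet cell proportions mixed over reference
  profiles, covariate effects (age, sex, smoking proxy, ancestry shift) and
  exposure effects added on the M scale, Gaussian M-scale noise;
* a **paired arm** (default 5 donors x 2 conditions) with a per-donor random
  baseline shared by the paired columns and effects applied only to the
  deprived condition.

Effects are additive on the M scale; beta differences are an *output* of the
simulation, not an input. All generators are pure functions of their
arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellReference, CpGMap, EffectSpec, MethylationDataset
from .qc import beta_to_m, clip_betas, m_to_beta

__all__ = [
    "WHOLE_BLOOD_CELL_TYPES",
    "CohortModel",
    "generate_map",
    "make_cell_reference",
    "generate_cohort",
    "generate_paired",
    "generate_qc_artifacts",
    "choose_effect_regions",
    "delta_m_for_delta_beta",
    "SimulatedStudy",
    "simulate_cross_design_study",
]

WHOLE_BLOOD_CELL_TYPES = ("Bcell", "CD8T", "CD4T", "NK", "Mono", "Gran")

# Rough leukocyte composition of adult whole blood, used to centre the
# Dirichlet prior on realistic proportions (granulocyte-dominated).
_BLOOD_FRACTIONS = np.array([0.05, 0.10, 0.15, 0.06, 0.08, 0.56])
_DIRICHLET_CONCENTRATION = 50.0


def generate_map(n_chrom: int, cpgs_per_chrom: int, mean_gap_bp: float = 300.0,
                 seed: int = 0, start_pos: int = 10_000) -> CpGMap:
    """Random CpG map with exponential inter-probe gaps (rounded, min 2 bp).

    The exponential gap distribution produces both tight probe clusters and
    gaps beyond any DMR max-gap threshold, so run-splitting logic is
    exercised by construction.
    """
    if n_chrom < 1 or cpgs_per_chrom < 1:
        raise ValueError("counts must be >= 1")
    if mean_gap_bp <= 0:
        raise ValueError("mean_gap_bp must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    probe = 0
    for c in range(1, n_chrom + 1):
        gaps = np.maximum(2, np.rint(rng.exponential(mean_gap_bp, cpgs_per_chrom - 1))).astype(int)
        pos = start_pos + np.concatenate([[0], np.cumsum(gaps)])
        for p in pos:
            rows.append((f"cg{probe:08d}", f"chr{c}", int(p)))
            probe += 1
    return CpGMap(pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]))


def make_cell_reference(cpg_map: CpGMap, n_cell_types: int = 6, seed: int = 0,
                        names: Sequence[str] | None = None,
                        informative_fraction: float = 0.15) -> CellReference:
    """Synthetic reference profiles with a realistic discrimination structure.

    Most CpGs carry the same (bimodal, Beta(0.4, 0.4)) methylation level in
    every leukocyte subtype; a minority (``informative_fraction``, default
    15%) are cell-type discriminating, with independent Beta(0.5, 0.5)
    levels per subtype — these are the probes that make reference-based
    deconvolution identifiable, mirroring how sorted-cell reference panels
    behave. Values clipped to [0.02, 0.98].
    """
    if names is None:
        names = WHOLE_BLOOD_CELL_TYPES[:n_cell_types] if n_cell_types <= 6 else \
            tuple(f"cell{i}" for i in range(n_cell_types))
    if len(names) != n_cell_types:
        raise ValueError("names length must equal n_cell_types")
    if not 0 < informative_fraction <= 1:
        raise ValueError("informative_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    G = len(cpg_map)
    base = rng.beta(0.4, 0.4, size=G)
    vals = np.tile(base[:, None], (1, n_cell_types))
    n_inf = max(n_cell_types, int(round(informative_fraction * G)))
    informative = rng.choice(G, size=min(n_inf, G), replace=False)
    vals[informative] = rng.beta(0.5, 0.5, size=(len(informative), n_cell_types))
    profiles = pd.DataFrame(np.clip(vals, 0.02, 0.98),
                            index=cpg_map.probe_ids, columns=list(names))
    return CellReference(profiles)


@dataclass
class CohortModel:
    """Generative model of the cohort arm.

    ``covariate_effects`` are slopes on the M scale: ``age`` and ``sex`` act
    on every probe; ``smoking`` acts on ``smoking_probes`` (scaled by the
    per-sample smoking level); ``population`` shifts ``ancestry_probes`` for
    the second population. ``fixed_proportions`` overrides the Dirichlet
    draw with one shared composition (useful for noiseless checks).
    """

    cell_reference: CellReference
    n_exposed: int = 25
    n_control: int = 54
    dirichlet_alpha: np.ndarray | None = None
    covariate_effects: Mapping[str, float] = dc_field(
        default_factory=lambda: {"age": 0.005, "sex": 0.05, "smoking": 0.5, "population": 0.5})
    noise_sd: float = 0.05
    seed: int = 0
    fixed_proportions: np.ndarray | None = None
    smoking_probes: tuple = ()
    ancestry_probes: tuple = ()
    clip_eps: float = 1e-6
    # sampling of demographics; exposed individuals are slightly older,
    # mirroring a birth-window defined exposure. The within-group age spread
    # is kept wide enough that age and exposure remain separately
    # identifiable in the adjusted regression (a birth-window exposure with
    # near-zero within-group age variance makes the two collinear and
    # destroys per-CpG power for any effect size).
    age_mean_exposed: float = 50.3
    age_sd_exposed: float = 2.0
    age_mean_control: float = 46.8
    age_sd_control: float = 2.0
    male_fraction: float = 0.4

    def __post_init__(self):
        if self.n_exposed + self.n_control < 4:
            raise ValueError("need at least 4 samples in total")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        k = len(self.cell_reference.cell_names)
        if self.dirichlet_alpha is None:
            if k == 6:
                self.dirichlet_alpha = _BLOOD_FRACTIONS * _DIRICHLET_CONCENTRATION
            else:
                self.dirichlet_alpha = np.full(k, 2.0)
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if self.dirichlet_alpha.shape != (k,) or np.any(self.dirichlet_alpha <= 0):
            raise ValueError("dirichlet_alpha must be positive, one entry per cell type")
        if self.fixed_proportions is not None:
            w = np.asarray(self.fixed_proportions, dtype=float)
            if w.shape != (k,) or np.any(w < 0) or abs(w.sum() - 1) > 1e-8:
                raise ValueError("fixed_proportions must be a length-k simplex vector")
            self.fixed_proportions = w


def generate_cohort(cpg_map: CpGMap, model: CohortModel,
                    effects: Sequence[EffectSpec] = ()) -> MethylationDataset:
    """Simulate the cohort arm.

    Per sample: baseline beta = reference profiles mixed by the sample's cell
    proportions; converted to M; covariate and exposure effects added on the
    M scale (exposure effects only at effect-region probes of exposed
    samples); Gaussian noise added; converted back to beta and clipped. True
    cell proportions and covariates are recorded in the sample sheet.
    """
    ref = model.cell_reference
    missing = set(cpg_map.probe_ids) - set(ref.probe_ids)
    if missing:
        raise ValueError(f"cell reference is missing {len(missing)} map probes")
    R = ref.profiles.loc[cpg_map.probe_ids].to_numpy()  # probes x cells
    rng = np.random.default_rng(model.seed)
    n = model.n_exposed + model.n_control
    exposure = np.concatenate([np.ones(model.n_exposed, int), np.zeros(model.n_control, int)])
    sample_ids = [f"fam{i + 1:03d}" for i in range(model.n_exposed)] + \
                 [f"ctl{i + 1:03d}" for i in range(model.n_control)]

    age = np.where(
        exposure == 1,
        rng.normal(model.age_mean_exposed, model.age_sd_exposed, n),
        rng.normal(model.age_mean_control, model.age_sd_control, n),
    )
    sex = (rng.random(n) < model.male_fraction).astype(int)  # 1 = male
    smoking = rng.normal(0.0, 1.0, n)
    population = (rng.random(n) < 0.5).astype(int)

    if model.fixed_proportions is not None:
        W = np.tile(model.fixed_proportions, (n, 1))
    else:
        W = rng.dirichlet(model.dirichlet_alpha, size=n)
    baseline = R @ W.T  # probes x samples
    M = beta_to_m(clip_betas(baseline, model.clip_eps))

    eff = dict(model.covariate_effects)
    M = M + eff.get("age", 0.0) * (age - age.mean())[None, :]
    M = M + eff.get("sex", 0.0) * sex[None, :]
    if model.smoking_probes:
        idx = cpg_map.indices_of(model.smoking_probes)
        M[idx, :] += eff.get("smoking", 0.0) * smoking[None, :]
    if model.ancestry_probes:
        idx = cpg_map.indices_of(model.ancestry_probes)
        M[idx, :] += eff.get("population", 0.0) * population[None, :]

    exposed_cols = np.flatnonzero(exposure == 1)
    for spec in effects:
        gi = spec.global_indices(cpg_map)
        M[np.ix_(gi, exposed_cols)] += spec.delta_m

    if model.noise_sd > 0:
        M = M + rng.normal(0.0, model.noise_sd, M.shape)

    betas = pd.DataFrame(clip_betas(m_to_beta(M), model.clip_eps),
                         index=cpg_map.probe_ids, columns=sample_ids)
    sheet = pd.DataFrame(
        {"exposure": exposure, "age": age, "sex": sex,
         "smoking": smoking, "population": population},
        index=pd.Index(sample_ids, name="sample_id"))
    for j, name in enumerate(ref.cell_names):
        sheet[f"true_{name}"] = W[:, j]
    return MethylationDataset(betas=betas, sample_sheet=sheet, cpg_map=cpg_map)


def generate_paired(cpg_map: CpGMap, n_donors: int = 5,
                    effects: Sequence[EffectSpec] = (), donor_sd: float = 0.3,
                    noise_sd: float = 0.1, seed: int = 0,
                    baseline_beta: np.ndarray | None = None,
                    clip_eps: float = 1e-6) -> MethylationDataset:
    """Simulate the paired in vitro arm: per donor one baseline methylome
    (probe-wise random intercept on the M scale, sd ``donor_sd``) shared by the
    paired 'normal' and 'deprived' columns; effects applied to the deprived
    column only; independent M-scale noise per column."""
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    if donor_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    G = len(cpg_map)
    if baseline_beta is None:
        baseline_beta = rng.beta(2.0, 2.0, G)
    baseline_beta = np.asarray(baseline_beta, dtype=float)
    if baseline_beta.shape != (G,):
        raise ValueError("baseline_beta must have one value per map probe")
    base_m = beta_to_m(clip_betas(baseline_beta, clip_eps))

    cols, col_meta = [], []
    M = np.empty((G, 2 * n_donors))
    for d in range(n_donors):
        donor = f"donor{d + 1:02d}"
        intercept = rng.normal(0.0, donor_sd, G) if donor_sd > 0 else np.zeros(G)
        m_donor = base_m + intercept
        m_norm = m_donor.copy()
        m_dep = m_donor.copy()
        for spec in effects:
            gi = spec.global_indices(cpg_map)
            m_dep[gi] += spec.delta_m
        if noise_sd > 0:
            m_norm = m_norm + rng.normal(0.0, noise_sd, G)
            m_dep = m_dep + rng.normal(0.0, noise_sd, G)
        M[:, 2 * d] = m_norm
        M[:, 2 * d + 1] = m_dep
        cols += [f"{donor}_normal", f"{donor}_deprived"]
        col_meta += [(donor, "normal"), (donor, "deprived")]

    betas = pd.DataFrame(clip_betas(m_to_beta(M), clip_eps),
                         index=cpg_map.probe_ids, columns=cols)
    # one male among five donors, as in a small fibroblast panel
    donor_sex = {f"donor{d + 1:02d}": (1 if d == 0 else 0) for d in range(n_donors)}
    donor_age = {f"donor{d + 1:02d}": a
                 for d, a in enumerate(rng.normal(38.4, 7.0, n_donors))}
    sheet = pd.DataFrame(
        {"donor": [m[0] for m in col_meta],
         "condition": [m[1] for m in col_meta],
         "exposure": [1 if m[1] == "deprived" else 0 for m in col_meta]},
        index=pd.Index(cols, name="sample_id"))
    sheet["sex"] = sheet["donor"].map(donor_sex)
    sheet["age"] = sheet["donor"].map(donor_age)
    return MethylationDataset(betas=betas, sample_sheet=sheet, cpg_map=cpg_map)


def generate_qc_artifacts(dataset: MethylationDataset, probe_fail_rate: float = 0.0,
                          sample_fail_ids: Sequence[str] = (), seed: int = 0,
                          probe_fail_fraction: float = 0.1,
                          sample_fail_probe_fraction: float = 0.02,
                          fail_cells: Mapping[str, int] | None = None,
                          fail_kind: str = "both") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection-p and bead-count matrices matched to ``dataset``.

    Passing cells: detection p ~ U(0, 1e-4), bead counts in [5, 30]. Failing
    cells get detection p ~ U(0.02, 0.5) and/or bead counts in {0, 1, 2}
    according to ``fail_kind`` ('detection', 'bead' or 'both').

    * ``probe_fail_rate``: fraction of probes made to fail in a random
      ``probe_fail_fraction`` share of sample columns;
    * ``fail_cells``: explicit probe id -> number of failing sample columns;
    * ``sample_fail_ids``: samples failed in ``sample_fail_probe_fraction`` of
      probes (detection failures).
    """
    if not 0 <= probe_fail_rate <= 1:
        raise ValueError("probe_fail_rate must lie in [0, 1]")
    if fail_kind not in ("detection", "bead", "both"):
        raise ValueError("fail_kind must be 'detection', 'bead' or 'both'")
    unknown = set(sample_fail_ids) - set(dataset.betas.columns)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    G, n = dataset.betas.shape
    det = rng.uniform(0.0, 1e-4, (G, n))
    beads = rng.integers(5, 31, (G, n)).astype(int)

    fail_mask = np.zeros((G, n), dtype=bool)
    probe_pos = {p: i for i, p in enumerate(dataset.betas.index)}
    n_fail_cols = max(1, math.ceil(probe_fail_fraction * n))
    flagged = np.flatnonzero(rng.random(G) < probe_fail_rate) if probe_fail_rate > 0 else []
    for gi in flagged:
        fail_mask[gi, rng.choice(n, n_fail_cols, replace=False)] = True
    if fail_cells:
        for probe, count in fail_cells.items():
            if probe not in probe_pos:
                raise ValueError(f"unknown probe id: {probe}")
            if not 0 <= count <= n:
                raise ValueError("failing column count out of range")
            fail_mask[probe_pos[probe], rng.choice(n, count, replace=False)] = True
    if sample_fail_ids:
        n_fail_probes = max(1, math.ceil(sample_fail_probe_fraction * G))
        col_pos = {c: j for j, c in enumerate(dataset.betas.columns)}
        for sid in sample_fail_ids:
            fail_mask[rng.choice(G, n_fail_probes, replace=False), col_pos[sid]] = True

    if fail_kind in ("detection", "both"):
        det[fail_mask] = rng.uniform(0.02, 0.5, int(fail_mask.sum()))
    if fail_kind in ("bead", "both"):
        beads[fail_mask] = rng.integers(0, 3, int(fail_mask.sum()))
    det_df = pd.DataFrame(det, index=dataset.betas.index, columns=dataset.betas.columns)
    bead_df = pd.DataFrame(beads, index=dataset.betas.index, columns=dataset.betas.columns)
    return det_df, bead_df


def delta_m_for_delta_beta(delta_beta: float, beta0: float = 0.5) -> float:
    """M-scale shift that moves a beta value from ``beta0`` to ``beta0 + delta_beta``."""
    b1 = beta0 + delta_beta
    if not (0 < beta0 < 1 and 0 < b1 < 1):
        raise ValueError("beta0 and beta0 + delta_beta must lie in (0, 1)")
    return math.log2(b1 / (1 - b1)) - math.log2(beta0 / (1 - beta0))


def choose_effect_regions(cpg_map: CpGMap, sizes: Sequence[int], delta_ms: Sequence[float],
                          seed: int = 0, max_gap: int = 1000,
                          min_separation: int = 10,
                          isolated: bool = True) -> list[EffectSpec]:
    """Pick non-overlapping effect regions that each map to exactly one
    candidate DMR run: internal inter-CpG gaps are all <= ``max_gap``, and
    (with ``isolated``, the default) the gaps to the flanking probes exceed
    ``max_gap``, so a spiked region can neither split nor absorb or merge
    with neighbouring probes during run formation. Regions also keep at
    least ``min_separation`` probes from one another."""
    if len(sizes) != len(delta_ms):
        raise ValueError("sizes and delta_ms must have equal length")
    rng = np.random.default_rng(seed)
    df = cpg_map.table
    taken: list[tuple[int, int]] = []  # global index spans incl. separation
    specs: list[EffectSpec] = []
    for size, dm in zip(sizes, delta_ms):
        candidates = []
        for chrom in cpg_map.chromosomes:
            sl = cpg_map.chrom_slice(chrom)
            pos = df["pos"].to_numpy()[sl]
            if len(pos) < size:
                continue
            for i in range(len(pos) - size + 1):
                if size > 1 and not np.all(np.diff(pos[i:i + size]) <= max_gap):
                    continue
                if isolated:
                    if i > 0 and pos[i] - pos[i - 1] <= max_gap:
                        continue
                    if i + size < len(pos) and pos[i + size] - pos[i + size - 1] <= max_gap:
                        continue
                g0, g1 = sl.start + i, sl.start + i + size
                if all(g1 + min_separation <= t0 or g0 >= t1 + min_separation
                       for t0, t1 in taken):
                    candidates.append((chrom, i, g0, g1))
        if not candidates:
            raise ValueError(f"no feasible region of {size} CpGs with gaps <= {max_gap}")
        chrom, i, g0, g1 = candidates[rng.integers(len(candidates))]
        taken.append((g0, g1))
        specs.append(EffectSpec(chrom=chrom, start=i, n_cpgs=size, delta_m=dm))
    return specs


@dataclass
class SimulatedStudy:
    """A complete closed-loop study: both arms plus the matched covariate inputs."""

    cpg_map: CpGMap
    cohort: MethylationDataset
    paired: MethylationDataset
    reference: CellReference
    smoking_weights: pd.Series
    ancestry_probes: tuple
    cohort_effects: tuple
    paired_effects: tuple


def simulate_cross_design_study(n_probes: int = 5000, n_chrom: int = 4,
                                mean_gap_bp: float = 300.0,
                                cohort_effects: Sequence[EffectSpec] = (),
                                paired_effects: Sequence[EffectSpec] = (),
                                n_exposed: int = 25, n_control: int = 54,
                                n_donors: int = 5, cohort_noise_sd: float = 0.05,
                                paired_noise_sd: float = 0.1, donor_sd: float = 0.3,
                                n_smoking_probes: int = 10, n_ancestry_probes: int = 40,
                                seed: int = 0,
                                cpg_map: CpGMap | None = None) -> SimulatedStudy:
    """Generate a two-arm study on a shared map, together with the matched
    cell reference, smoking weight list and ancestry probe list needed to run
    the full pipeline closed-loop (no external annotation).

    Pass a prebuilt ``cpg_map`` when effect regions were chosen against it
    (e.g. via :func:`choose_effect_regions`); otherwise a fresh map is drawn
    from the seed and effect indices refer to that map.
    """
    root = np.random.default_rng(seed)
    s_map, s_ref, s_cohort, s_paired, s_pick = root.integers(2**31, size=5)
    if cpg_map is None:
        cpgs_per_chrom = max(2, n_probes // n_chrom)
        cpg_map = generate_map(n_chrom, cpgs_per_chrom, mean_gap_bp, seed=int(s_map))
    reference = make_cell_reference(cpg_map, seed=int(s_ref))

    effect_idx: set[int] = set()
    for spec in list(cohort_effects) + list(paired_effects):
        effect_idx.update(spec.global_indices(cpg_map).tolist())
    free = np.array([i for i in range(len(cpg_map)) if i not in effect_idx])
    pick_rng = np.random.default_rng(int(s_pick))
    picked = pick_rng.choice(free, n_smoking_probes + n_ancestry_probes, replace=False)
    probe_arr = cpg_map.probe_ids.to_numpy()
    smoking_probes = tuple(probe_arr[picked[:n_smoking_probes]])
    ancestry_probes = tuple(probe_arr[picked[n_smoking_probes:]])

    model = CohortModel(cell_reference=reference, n_exposed=n_exposed,
                        n_control=n_control, noise_sd=cohort_noise_sd,
                        seed=int(s_cohort), smoking_probes=smoking_probes,
                        ancestry_probes=ancestry_probes)
    cohort = generate_cohort(cpg_map, model, cohort_effects)
    paired = generate_paired(cpg_map, n_donors=n_donors, effects=paired_effects,
                             donor_sd=donor_sd, noise_sd=paired_noise_sd,
                             seed=int(s_paired))
    weights = pd.Series(1.0, index=pd.Index(smoking_probes, name="probe_id"),
                        name="weight")
    return SimulatedStudy(cpg_map=cpg_map, cohort=cohort, paired=paired,
                          reference=reference, smoking_weights=weights,
                          ancestry_probes=ancestry_probes,
                          cohort_effects=tuple(cohort_effects),
                          paired_effects=tuple(paired_effects))
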
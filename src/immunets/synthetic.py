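"""Synthetic data generators with planted ground truth.

Three generators emulate the three data modalities the pipeline consumes:

* a multi-cell-type expression compendium (log2-like additive scale,
  microarray-style) with co-regulated gene modules planted in chosen cell
  types — the substrate for network construction;
* treatment cohorts (non-negative FPKM/TPM-like scale) with RECIST
  response labels and genes planted at a chosen fold change between
  responders and non-responders — the substrate for differential
  expression;
* survival cohorts drawn from a proportional-hazards model with planted
  per-gene log-hazard coefficients — the substrate for risk models.

Every generator is deterministic given its spec (which embeds a seed),
and returns the ground truth needed to score downstream recovery.

Module co-expression is induced by a single shared latent factor per
(module, cell type). With i.i.d. Gaussian noise of standard deviation
``sigma`` and latent loading ``a``, the pairwise correlation between two
module genes is ``a^2 / (a^2 + sigma^2)``; the loading is therefore
solved analytically from the target correlation ``r`` as
``a = sigma * sqrt(r / (1 - r))``. In the noiseless limit (sigma = 0)
any positive loading yields r = 1 exactly, and the declared latent
amplitude is used directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

# --------------------------------------------------------------------------
# compendium
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModule:
    """A co-regulated gene module planted in one or more cell types."""

    gene_ids: tuple
    active_cell_types: tuple
    latent_amplitude: float = 2.0
    within_module_correlation: float = 0.95

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(
            self, "active_cell_types", tuple(self.active_cell_types)
        )
        if len(self.gene_ids) < 2:
            raise ValueError("a module needs at least 2 genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids within a module")
        if not 0 < self.within_module_correlation < 1:
            raise ValueError("within_module_correlation must be in (0, 1)")
        if self.latent_amplitude <= 0:
            raise ValueError("latent_amplitude must be positive")


@dataclass(frozen=True)
class CompendiumSpec:
    """Design of a synthetic immune-cell expression compendium.

    The layout mirrors a multi-cell-type resting/activated/differentiated
    design: ``n_cell_types`` cell types, each assayed in
    ``states_per_type`` states with ``samples_per_state`` replicates.
    """

    n_cell_types: int = 5
    states_per_type: int = 3
    samples_per_state: int = 10
    n_background_genes: int = 500
    modules: tuple = ()
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # fraction of latent-factor variance carried by between-state shifts
    # (co-regulation across activation states, which the ANOVA screen
    # detects); the rest is per-sample
    state_variance_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if self.samples_per_state < 3:
            raise ValueError(
                "samples_per_state must be >= 3 (correlation needs >= 3 points)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.state_variance_fraction < 1:
            raise ValueError("state_variance_fraction must be in [0, 1)")
        cell_types = set(self.cell_types)
        seen: set = set()
        for mod in self.modules:
            overlap = seen.intersection(mod.gene_ids)
            if overlap:
                raise ValueError(
                    f"gene ids shared between modules: {sorted(overlap)[:5]}"
                )
            seen.update(mod.gene_ids)
            unknown = set(mod.active_cell_types) - cell_types
            if unknown:
                raise ValueError(
                    f"module references unknown cell types: {sorted(unknown)}"
                )

    @property
    def cell_types(self) -> list:
        return [f"CT{i + 1}" for i in range(self.n_cell_types)]

    @property
    def states(self) -> list:
        return [f"S{i + 1}" for i in range(self.states_per_type)]


@dataclass
class CompendiumTruth:
    """Ground truth of a simulated compendium."""

    modules: tuple
    # cell type -> set of genes co-regulated there
    module_genes_by_cell_type: dict

    def expected_edges(self, cell_type: str) -> set:
        """All within-module unordered gene pairs co-regulated in `cell_type`."""
        edges = set()
        for mod in self.modules:
            if cell_type in mod.active_cell_types:
                genes = sorted(mod.gene_ids)
                for i in range(len(genes)):
                    for j in range(i + 1, len(genes)):
                        edges.add((genes[i], genes[j]))
        return edges


def latent_loading(target_r: float, noise_sd: float, amplitude: float) -> float:
    """Latent-factor loading that realises `target_r` at noise level `noise_sd`."""
    if noise_sd == 0:
        return amplitude
    return noise_sd * np.sqrt(target_r / (1.0 - target_r))


def simulate_compendium(spec: CompendiumSpec):
    """Simulate a compendium; returns (ExpressionMatrix, CompendiumTruth).

    Background genes are pure noise around a per-gene baseline. Module
    genes additionally carry, within each active cell type, a constant
    mean offset (guaranteeing differential expression across cell-type x
    state groups) and a shared per-sample latent factor calibrated to
    the module's target pairwise correlation.
    """
    rng = np.random.default_rng(spec.seed)
    module_genes = [g for m in spec.modules for g in m.gene_ids]
    background = [f"BG{i + 1:05d}" for i in range(spec.n_background_genes)]
    clash = set(module_genes).intersection(background)
    if clash:
        raise ValueError(f"module gene ids collide with background ids: {clash}")
    genes = module_genes + background

    sample_ids, cell_col, state_col = [], [], []
    for ct in spec.cell_types:
        for st in spec.states:
            for k in range(spec.samples_per_state):
                sample_ids.append(f"{ct}_{st}_{k + 1}")
                cell_col.append(ct)
                state_col.append(st)
    n_samples = len(sample_ids)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(len(genes), n_samples)
    )

    cell_arr = np.array(cell_col)
    state_arr = np.array(state_col)
    gene_index = {g: i for i, g in enumerate(genes)}
    by_cell_type: dict = {ct: set() for ct in spec.cell_types}
    f_state = spec.state_variance_fraction if spec.states_per_type > 1 else 0.0
    for mod in spec.modules:
        rows = np.array([gene_index[g] for g in mod.gene_ids])
        a = latent_loading(
            mod.within_module_correlation, spec.noise_sd, mod.latent_amplitude
        )
        for ct in mod.active_cell_types:
            cols = np.flatnonzero(cell_arr == ct)
            # latent factor = standardized between-state shifts (the
            # differential regulation the ANOVA screen detects) plus
            # standardized per-sample variation; unit variance overall so
            # the target-correlation calibration holds exactly
            eps = rng.normal(0.0, 1.0, size=cols.size)
            eps = (eps - eps.mean()) / eps.std()
            if f_state > 0:
                u = rng.normal(0.0, 1.0, size=spec.states_per_type)
                u = (u - u.mean()) / u.std()
                state_idx = np.searchsorted(spec.states, state_arr[cols])
                z = np.sqrt(f_state) * u[state_idx] + np.sqrt(1 - f_state) * eps
            else:
                z = eps
            values[np.ix_(rows, cols)] += mod.latent_amplitude + a * z[None, :]
            by_cell_type[ct].update(mod.gene_ids)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        pd.DataFrame(
            {"cell_type": cell_col, "state": state_col}, index=sample_ids
        ),
    )
    return matrix, CompendiumTruth(spec.modules, by_cell_type)


# --------------------------------------------------------------------------
# treatment-response cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseCohortSpec:
    """Design of a synthetic nivolumab-style treatment cohort.

    Expression is on a non-negative linear (FPKM/TPM-like) scale:
    per-gene base abundances are log-normal, and patient-level values are
    the base scaled by multiplicative log-normal noise whose log-sd is
    ``dispersion`` (mean-preserving, so group-mean ratios of planted
    genes equal ``fold`` in expectation; at dispersion = 0 they equal
    ``fold`` exactly).
    """

    n_response: int = 12
    n_nonresponse: int = 12
    n_stable: int = 0
    n_genes: int = 500
    planted_up: tuple = ()
    planted_down: tuple = ()
    fold: float = 2.0
    dispersion: float = 0.5
    base_log_mean: float = 2.3
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_up", tuple(self.planted_up))
        object.__setattr__(self, "planted_down", tuple(self.planted_down))
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_response + self.n_nonresponse < 4:
            raise ValueError(
                "need at least 4 labelled patients for a rank test"
            )
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"genes planted both up and down: {sorted(overlap)}")
        known = set(self.gene_ids)
        missing = (set(self.planted_up) | set(self.planted_down)) - known
        if missing:
            raise ValueError(f"planted genes outside gene space: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class ResponseCohortTruth:
    planted_up: tuple
    planted_down: tuple
    fold: float


def simulate_response_cohort(spec: ResponseCohortSpec):
    """Simulate a response cohort; returns (ExpressionMatrix, truth).

    Sample annotations carry a RECIST code per patient: responders are
    labelled CR or PR (alternating), non-responders PD, and stable
    patients SD. SD patients receive unplanted (base) expression and are
    excluded from group testing downstream.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    base = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd, len(genes)))

    n_total = spec.n_response + spec.n_nonresponse + spec.n_stable
    recist = (
        ["CR" if i % 2 == 0 else "PR" for i in range(spec.n_response)]
        + ["PD"] * spec.n_nonresponse
        + ["SD"] * spec.n_stable
    )
    sample_ids = [f"P{i + 1:03d}" for i in range(n_total)]

    up = np.isin(genes, spec.planted_up)
    down = np.isin(genes, spec.planted_down)
    means = np.tile(base[:, None], (1, n_total))
    resp_cols = np.arange(spec.n_response)
    nonresp_cols = np.arange(spec.n_response, spec.n_response + spec.n_nonresponse)
    means[np.ix_(up, resp_cols)] *= spec.fold
    means[np.ix_(down, nonresp_cols)] *= spec.fold

    if spec.dispersion > 0:
        # mean-preserving multiplicative log-normal noise
        noise = np.exp(
            rng.normal(0.0, spec.dispersion, size=means.shape)
            - spec.dispersion**2 / 2.0
        )
    else:
        noise = 1.0
    values = means * noise

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        pd.DataFrame({"recist": recist}, index=sample_ids),
    )
    truth = ResponseCohortTruth(spec.planted_up, spec.planted_down, spec.fold)
    return matrix, truth


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalCohortSpec:
    """Design of a synthetic melanoma-like survival cohort.

    Event times follow an exponential proportional-hazards model:
    ``T ~ Exp(baseline_hazard * exp(lp))`` with linear predictor
    ``lp = sum_g beta_g x_g + beta_age (age - 60) + beta_stage (stage - 2)``
    (age and stage are centred so baseline_hazard is the hazard of a
    typical patient, in events per month). Censoring is an independent
    exponential with rate ``censor_rate``; observed time is the minimum.

    Gene expression is standard normal per gene; genes listed in
    ``bimodal`` instead draw a latent high/low component (probability
    1/2 each) separated by the given amount — used to plant
    mixture-stratifiable prognostic genes.
    """

    n_patients: int = 300
    betas: tuple = ()  # ((gene, beta), ...)
    beta_age: float = 0.0
    beta_stage: float = 0.0
    baseline_hazard: float = 0.02
    censor_rate: float = 0.01
    stage_probs: tuple = (0.2, 0.3, 0.45, 0.05)
    n_noise_genes: int = 0
    bimodal: tuple = ()  # ((gene, separation), ...)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "betas", tuple(tuple(b) for b in self.betas))
        object.__setattr__(self, "bimodal", tuple(tuple(b) for b in self.bimodal))
        object.__setattr__(self, "stage_probs", tuple(self.stage_probs))
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if len(self.stage_probs) != 4 or not np.isclose(sum(self.stage_probs), 1.0):
            raise ValueError("stage_probs must be 4 probabilities summing to 1")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")

    @property
    def gene_ids(self) -> list:
        named = [g for g, _ in self.betas]
        noise = [f"N{i + 1:04d}" for i in range(self.n_noise_genes)]
        return named + noise


@dataclass
class SurvivalTruth:
    betas: dict
    beta_age: float
    beta_stage: float


def simulate_survival_cohort(spec: SurvivalCohortSpec):
    """Simulate a survival cohort; returns (pandas.DataFrame, SurvivalTruth).

    The frame has one row per patient with columns ``time`` (months),
    ``event`` (bool), ``age`` (years), ``stage_code`` (1-4) and one
    column per gene.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    genes = spec.gene_ids
    bimodal = dict(spec.bimodal)

    expr = {}
    for g in genes:
        x = rng.normal(0.0, 1.0, n)
        if g in bimodal:
            x = x + bimodal[g] * rng.integers(0, 2, n)
        expr[g] = x

    age = rng.uniform(35.0, 85.0, n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=list(spec.stage_probs))

    betas = dict(spec.betas)
    lp = spec.beta_age * (age - 60.0) + spec.beta_stage * (stage - 2.0)
    for g, b in betas.items():
        lp = lp + b * expr[g]

    event_time = rng.exponential(1.0, n) / (spec.baseline_hazard * np.exp(lp))
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    if not event.any():
        warnings.warn("degenerate survival cohort: no events observed")

    data = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age,
            "stage_code": stage.astype(int),
            **{g: expr[g] for g in genes},
        },
        index=[f"PT{i + 1:04d}" for i in range(n)],
    )
    return data, SurvivalTruth(betas, spec.beta_age, spec.beta_stage)


# --------------------------------------------------------------------------
# reference network / annotation scaffolding for the focus stage
# --------------------------------------------------------------------------


def simulate_reference_network(
    truth: CompendiumTruth,
    extra_genes,
    p_edge: float = 0.02,
    p_module_edge: float = 1.0,
    seed: int = 0,
):
    """Build a HumanNet-like reference edge list embedding the planted modules.

    Module gene pairs are connected with probability ``p_module_edge``
    (cliques by default); all other pairs over the union of module genes
    and ``extra_genes`` are Erdos-Renyi with probability ``p_edge``.
    Returns a list of (gene_a, gene_b) tuples.
    """
    rng = np.random.default_rng(seed)
    module_genes = sorted({g for m in truth.modules for g in m.gene_ids})
    nodes = module_genes + [g for g in extra_genes if g not in set(module_genes)]
    module_pairs = set()
    for m in truth.modules:
        gs = sorted(m.gene_ids)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                module_pairs.add((gs[i], gs[j]))
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = tuple(sorted((nodes[i], nodes[j])))
            p = p_module_edge if pair in module_pairs else p_edge
            if rng.random() < p:
                edges.append(pair)
    return edges


def simulate_annotation(
    truth: CompendiumTruth, background, n_random_terms: int = 5, seed: int = 0
):
    """Gene -> term map: one term per planted module plus random terms."""
    rng = np.random.default_rng(seed)
    background = list(background)
    pairs = []
    for i, m in enumerate(truth.modules):
        for g in m.gene_ids:
            pairs.append((g, f"MODULE_TERM_{i + 1}"))
    for t in range(n_random_terms):
        size = int(rng.integers(5, max(6, len(background) // 10)))
        for g in rng.choice(background, size=min(size, len(background)), replace=False):
            pairs.append((str(g), f"RANDOM_TERM_{t + 1}"))
    return pairs
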
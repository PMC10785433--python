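"""Synthetic bi-fluorescent protoplast data with known ground truth.

Two levels of simulation mirror the two levels of the analysis:

* **Count level** — multinomial draws of the three gated categories straight
  from the misclassification model, for exercising the estimator under
  exactly its own assumptions.
* **Event level** — per-cell fluorescence and scatter measurements.  Each
  genotype population (RFP, GFP, GFP_RFP, WT) is a bivariate log-normal in
  the two readout channels (location/scale on the log10 scale, with
  correlation), plus independent Gaussian scatter/autofluorescence channels.
  A spiked sample draws each cell from the RFP population with probability
  ``s`` and from the GFP_RFP background otherwise, with a configurable
  fraction of low-quality debris events that fail the quality gate.

The default populations are an emulation, not published values: they place
the RFP cluster high in PE.CF594.A and low in FITC.A, the double-positive
background above both cuts, and overlap the clusters enough that
misclassification is nonzero by construction (so the adjustment matters).
Log-normal clusters keep every gate-crossing probability analytically
computable (:func:`implied_misclass_params`), which is what makes the
event-level pipeline checkable end to end.

The default spike design uses the levels of the bundled second flow run:
0%, 0.28%, 1.18% and 3.89%, plus the pure-RFP reference every series needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .fcs import EventTable
from .gating import ClassCounts, ThresholdSet, default_thresholds
from .model import ExperimentSeries, MisclassParams, SampleRole, category_probs

__all__ = [
    "ChannelModel",
    "PopulationModel",
    "PopulationSpec",
    "SpikeDesign",
    "DEFAULT_SPIKE_LEVELS",
    "default_population_spec",
    "default_spike_design",
    "simulate_counts",
    "simulate_series",
    "simulate_events",
    "sample_population",
    "implied_misclass_params",
    "series_from_counts",
]

#: Spike-in proportions of the bundled second flow run (control plus three
#: spiked samples), used as the default simulation design.
DEFAULT_SPIKE_LEVELS: tuple[float, ...] = (0.0, 0.0028, 0.0118, 0.0389)

GENOTYPES = ("RFP", "GFP", "GFP_RFP", "WT")


@dataclass(frozen=True)
class ChannelModel:
    """Gaussian location/scale for one linear-scale channel."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("channel sd must be positive")


@dataclass(frozen=True)
class PopulationModel:
    """One cell population: log10 fluorescence cluster plus scatter channels.

    ``log_mean``/``log_sd`` are the log10-scale location and scale of
    (FITC.A, PE.CF594.A); ``corr`` their correlation.  ``scatter`` maps the
    remaining channel names to linear Gaussian models.
    """

    log_mean: tuple[float, float]
    log_sd: tuple[float, float]
    corr: float = 0.0
    scatter: dict[str, ChannelModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sd):
            raise ValueError("log10 scales must be positive")
        if not -1.0 < self.corr < 1.0:
            raise ValueError("correlation must be in (-1, 1)")

    @property
    def log_cov(self) -> np.ndarray:
        s1, s2 = self.log_sd
        off = self.corr * s1 * s2
        return np.array([[s1 * s1, off], [off, s2 * s2]])


@dataclass(frozen=True)
class PopulationSpec:
    """Population models for the four genotypes plus a debris cluster.

    ``debris_fraction`` of events in every simulated sample come from the
    low-quality cluster (drawn independently of spike status); its channel
    locations are chosen to fail the quality bounds, so the two gate
    variants differ measurably on simulated data.
    """

    populations: dict[str, PopulationModel]
    debris: PopulationModel
    debris_fraction: float = 0.05
    spike_levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS

    def __post_init__(self) -> None:
        missing = set(GENOTYPES) - set(self.populations)
        if missing:
            raise ValueError(f"missing population models for {sorted(missing)}")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris fraction must be in [0, 1)")
        for name, pop in self.populations.items():
            for m in pop.log_mean:
                if not 2.0 <= m <= 4.0:
                    raise ValueError(
                        f"{name}: log10 fluorescence location {m} outside the dynamic range [2, 4]"
                    )


@dataclass(frozen=True)
class SpikeDesign:
    """Per-sample sizes and spike-in proportions for a simulated series."""

    n_events: tuple[int, ...]
    proportions: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_events) != len(self.proportions):
            raise ValueError("n_events and proportions must have equal lengths")
        if any(n <= 0 for n in self.n_events):
            raise ValueError("n_events must be positive")
        if any(not 0.0 <= s <= 1.0 for s in self.proportions):
            raise ValueError("spike proportions must be in [0, 1]")

    @property
    def roles(self) -> list[SampleRole]:
        out = []
        for s in self.proportions:
            if s == 0.0:
                out.append(SampleRole.CONTROL_ZERO)
            elif s == 1.0:
                out.append(SampleRole.PURE_ONE)
            else:
                out.append(SampleRole.UNKNOWN)
        return out


_PROTOPLAST_SCATTER = {
    "FSC.H": ChannelModel(120_000.0, 25_000.0),
    "FSC.A": ChannelModel(140_000.0, 28_000.0),
    "SSC.H": ChannelModel(1_600.0, 500.0),
    "SSC.A": ChannelModel(1_900.0, 600.0),
    "BV605.A": ChannelModel(2_200.0, 550.0),
    "BV510.A": ChannelModel(2_100.0, 520.0),
}

_DEBRIS_SCATTER = {
    "FSC.H": ChannelModel(18_000.0, 9_000.0),
    "FSC.A": ChannelModel(22_000.0, 11_000.0),
    "SSC.H": ChannelModel(180.0, 120.0),
    "SSC.A": ChannelModel(240.0, 160.0),
    "BV605.A": ChannelModel(320.0, 180.0),
    "BV510.A": ChannelModel(300.0, 170.0),
}


def default_population_spec() -> PopulationSpec:
    """Default emulated populations.

    RFP sits high in PE.CF594.A (log10 ~ 3.45) and low in FITC.A; GFP_RFP is
    double-positive; GFP and GFP_RFP overlap in FITC.A (they are not
    separable on these channels); WT is low in both.  Cluster tails cross
    the gates, so both probability triples have off-diagonal mass.
    """
    pops = {
        "RFP": PopulationModel((2.30, 3.45), (0.16, 0.18), 0.30, dict(_PROTOPLAST_SCATTER)),
        "GFP": PopulationModel((3.20, 2.45), (0.20, 0.20), 0.30, dict(_PROTOPLAST_SCATTER)),
        "GFP_RFP": PopulationModel((3.20, 3.30), (0.15, 0.20), 0.40, dict(_PROTOPLAST_SCATTER)),
        "WT": PopulationModel((2.25, 2.30), (0.18, 0.18), 0.20, dict(_PROTOPLAST_SCATTER)),
    }
    debris = PopulationModel((2.10, 2.10), (0.30, 0.30), 0.10, dict(_DEBRIS_SCATTER))
    return PopulationSpec(populations=pops, debris=debris)


def default_spike_design(n_events: int = 20_000, seed: int = 0) -> SpikeDesign:
    """Default series: control (s=0), pure-RFP reference (s=1), and the
    three bundled spike levels (0.28%, 1.18%, 3.89%)."""
    props = (0.0, 1.0) + DEFAULT_SPIKE_LEVELS[1:]
    return SpikeDesign(n_events=(n_events,) * len(props), proportions=props, seed=seed)


# ---------------------------------------------------------------------------
# Count-level simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    params: MisclassParams,
    s: float,
    n: int,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
) -> ClassCounts:
    """Multinomial category counts of size ``n`` at spike-in ``s``."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = rng.multinomial(n, category_probs(params, s))
    return ClassCounts(sample_id, int(y[0]), int(y[1]), int(y[2]))


def series_from_counts(
    counts: Sequence[ClassCounts], proportions: Sequence[float], experiment_id: str = "sim"
) -> ExperimentSeries:
    """Assemble a series, assigning roles from the design proportions
    (0 -> control, 1 -> pure reference, interior -> unknown)."""
    roles = [
        SampleRole.CONTROL_ZERO if s == 0.0
        else SampleRole.PURE_ONE if s == 1.0
        else SampleRole.UNKNOWN
        for s in proportions
    ]
    return ExperimentSeries(experiment_id, tuple(zip(counts, roles)))


def simulate_series(
    params: MisclassParams,
    proportions: Sequence[float],
    n: int | Sequence[int],
    seed: int | np.random.Generator = 0,
    experiment_id: str = "sim",
) -> ExperimentSeries:
    """Simulate a whole experiment series at the count level."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = [n] * len(proportions) if np.isscalar(n) else list(n)
    counts = [
        simulate_counts(params, s, sizes[i], rng, sample_id=f"{experiment_id}-l{i + 1}")
        for i, s in enumerate(proportions)
    ]
    return series_from_counts(counts, proportions, experiment_id)


# ---------------------------------------------------------------------------
# Event-level simulation
# ---------------------------------------------------------------------------

_FLUOR_CHANNELS = ("FITC.A", "PE.CF594.A")


def sample_population(pop: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` events from one population; columns are the fluorescence
    channels followed by the population's scatter channels."""
    logs = rng.multivariate_normal(pop.log_mean, pop.log_cov, size=n)
    fluor = np.power(10.0, logs)
    cols = [fluor]
    for cm in pop.scatter.values():
        cols.append(rng.normal(cm.mean, cm.sd, size=(n, 1)))
    return np.hstack(cols)


def simulate_events(spec: PopulationSpec, design: SpikeDesign) -> list[EventTable]:
    """Simulate one event table per design sample.

    Each cell is debris with probability ``spec.debris_fraction``; otherwise
    it comes from the RFP population with probability ``s`` and from the
    GFP_RFP background with probability ``1 - s``.  Every table carries an
    ``origin`` provenance array (``"RFP"``, ``"GFP_RFP"``, ``"debris"``) for
    testing only; it is not written by the CSV exporter.
    """
    rng = np.random.default_rng(design.seed)
    channels = list(_FLUOR_CHANNELS) + list(_PROTOPLAST_SCATTER)
    tables = []
    for k, (n, s) in enumerate(zip(design.n_events, design.proportions)):
        u = rng.random(n)
        is_debris = u < spec.debris_fraction
        is_rfp = ~is_debris & (rng.random(n) < s)
        origin = np.where(is_debris, "debris", np.where(is_rfp, "RFP", "GFP_RFP"))
        events = np.empty((n, len(channels)))
        for name, mask in (("debris", is_debris), ("RFP", is_rfp),
                           ("GFP_RFP", ~is_debris & ~is_rfp)):
            m = int(mask.sum())
            if m == 0:
                continue
            pop = spec.debris if name == "debris" else spec.populations[name]
            events[mask] = sample_population(pop, m, rng)
        tables.append(EventTable(f"sim-l{k + 1}", list(channels), events, origin=origin))
    return tables


# ---------------------------------------------------------------------------
# Analytic gate-crossing probabilities
# ---------------------------------------------------------------------------


def _rect_prob(pop: PopulationModel, fitc_win: tuple[float, float],
               pe_win: tuple[float, float]) -> float:
    """P(FITC in window, PE in window) for a bivariate log-normal cluster."""
    mvn = stats.multivariate_normal(mean=pop.log_mean, cov=pop.log_cov)
    a, b = np.log10(fitc_win[0]), np.log10(fitc_win[1])
    c, d = np.log10(pe_win[0]), np.log10(pe_win[1])
    return float(mvn.cdf([b, d]) - mvn.cdf([a, d]) - mvn.cdf([b, c]) + mvn.cdf([a, c]))


def population_category_probs(pop: PopulationModel,
                              thresholds: ThresholdSet | None = None) -> np.ndarray:
    """Exact (RFP, GFP+GFP_RFP, WT) classification probabilities for one
    population under the fluorescence gates — the closed-form counterpart of
    simulating events and gating them."""
    thresholds = thresholds or default_thresholds("rfp_gfp_only")
    g = thresholds.fluorescence[thresholds.gfp_channel]
    r = thresholds.fluorescence[thresholds.rfp_channel]
    lg = stats.norm(pop.log_mean[0], pop.log_sd[0])
    lr = stats.norm(pop.log_mean[1], pop.log_sd[1])
    p_gfp = lg.cdf(np.log10(g[1])) - lg.cdf(np.log10(g[0]))   # marginal GFP-positive
    p_rfp = lr.cdf(np.log10(r[1])) - lr.cdf(np.log10(r[0]))   # marginal RFP-positive
    p_both = _rect_prob(pop, g, r)
    p_rfp_only = p_rfp - p_both
    p_gfp_any = p_gfp  # GFP-only + double positive = all GFP-positive cells
    p_wt = 1.0 - p_rfp_only - p_gfp_any
    return np.array([p_rfp_only, p_gfp_any, p_wt])


def implied_misclass_params(spec: PopulationSpec,
                            thresholds: ThresholdSet | None = None) -> MisclassParams:
    """True p/q triples implied by a population spec (debris excluded).

    ``p`` comes from the RFP population, ``q`` from the GFP_RFP background;
    this is the ground truth the event-level pipeline should recover once
    the quality gate has removed the debris cluster.
    """
    p = population_category_probs(spec.populations["RFP"], thresholds)
    q = population_category_probs(spec.populations["GFP_RFP"], thresholds)
    return MisclassParams(tuple(p / p.sum()), tuple(q / q.sum()))
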
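"""Synthetic mesocosm communities along a drought gradient, with known truth.

Emulates a 21-channel stream-mesocosm experiment in which flow manipulation
creates a monotone gradient of drought intensity. Four physical stressors
(wetted area, water volume, flow, maximum temperature range) covary with a
latent gradient; genera drawn from trait archetypes respond to the gradient
with null, linear or logistic (threshold) abundance curves. Because every
response's shape and breakpoint are recorded, the generator supports
controlled recovery experiments for the downstream threshold analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .traits import RAW_SCHEMA, SIZE_CLASS_BOUNDS, schema_columns

STRESSORS = ("wetted_area", "water_volume", "flow", "max_temp_range")

#: Printed stressor endpoints of the mesocosm gradient, (benign, severe):
#: wetted area m^2, water volume m^3, flow L/s, max temperature range degC.
DEFAULT_STRESSOR_RANGES: dict[str, tuple[float, float]] = {
    "wetted_area": (6.5, 0.25),
    "water_volume": (1.9, 0.001),
    "flow": (2.2, 0.001),
    "max_temp_range": (6.0, 40.0),
}

RESPONSE_SHAPES = ("null", "linear_up", "linear_down", "threshold_up", "threshold_down")


@dataclass(frozen=True)
class ResponseSpec:
    """Shape of an expected-abundance response to the latent gradient.

    ``steepness`` is the maximum slope of the response curve after both
    axes are rescaled to [0, 1] - the scale on which the |slope| > 1
    threshold criterion operates - so responses can be placed above or
    below the detection criterion by construction. Only threshold shapes
    use ``breakpoint`` (the logistic centre) and ``steepness``.
    """

    shape: str = "null"
    breakpoint: float | None = None
    steepness: float = 3.0
    effect_size: float = 1.0

    def __post_init__(self):
        if self.shape not in RESPONSE_SHAPES:
            raise ValueError(f"unknown response shape {self.shape!r}")
        if self.shape.startswith("threshold"):
            if self.breakpoint is None or not 0 < self.breakpoint < 1:
                raise ValueError("threshold shapes need a breakpoint in (0, 1)")
            if self.steepness <= 0:
                raise ValueError("steepness must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated response."""

    response_id: str
    archetype: str
    shape: str
    breakpoint: float | None
    #: gradient interval where the noiseless rescaled curve has |slope| > 1
    #: (the analytic estimand of zone detection), or None.
    analytic_zone: tuple[float, float] | None


#: Trait archetypes loosely modelled on the functional groups of lowland
#: stream invertebrates: very large crawling shredders (large caddisflies),
#: tegument-breathing aquatic dispersers (leeches, flatworms),
#: spiracle-breathing dipterans, small eurythermic dietary generalists and
#: multivoltine cold-stenotherm chironomids. Affinities follow RAW_SCHEMA
#: block order. Each archetype has exactly one high-margin marker trait
#: ("defining trait"); all other trait states are shared between at least
#: two archetypes.
ARCHETYPES: dict[str, dict[str, list[float]]] = {
    "very_large_crawler": dict(
        body_size=[0.1, 0.2, 0.15, 0.55],
        voltinism=[0.2, 0.7, 0.1],
        reproduction=[0.0, 0.3, 0.7, 0.0],
        dispersal=[0.4, 0.5, 0.1, 0.0],
        resistance=[0.0, 0.0, 0.0],
        respiration=[0.2, 0.8, 0.0],
        locomotion=[0.1, 0.7, 0.1, 0.1, 0.0],
        diet=[1, 1, 1, 1, 1, 0, 0],
        thermal=[0.7, 0.2, 0.1],
    ),
    "tegument_aquatic_disperser": dict(
        body_size=[0.2, 0.7, 0.1, 0.0],
        voltinism=[0.2, 0.7, 0.1],
        reproduction=[0.0, 0.1, 0.2, 0.7],
        dispersal=[0.6, 0.3, 0.1, 0.0],
        resistance=[0.0, 0.0, 0.0],
        respiration=[0.8, 0.2, 0.0],
        locomotion=[0.1, 0.7, 0.1, 0.1, 0.0],
        diet=[0, 1, 0, 0, 0, 0, 1],
        thermal=[0.4, 0.5, 0.1],
    ),
    "spiracle_breather": dict(
        body_size=[0.2, 0.7, 0.1, 0.0],
        voltinism=[0.0, 0.2, 0.8],
        reproduction=[0.0, 0.3, 0.7, 0.0],
        dispersal=[0.0, 0.0, 0.25, 0.75],
        resistance=[0.0, 1.0, 1.0],
        respiration=[0.1, 0.1, 0.8],
        locomotion=[0.2, 0.15, 0.5, 0.15, 0.0],
        diet=[1, 1, 1, 1, 0, 1, 0],
        thermal=[0.1, 0.55, 0.35],
    ),
    "small_eurythermic_generalist": dict(
        body_size=[0.55, 0.35, 0.1, 0.0],
        voltinism=[0.0, 0.2, 0.8],
        reproduction=[0.8, 0.05, 0.15, 0.0],
        dispersal=[0.0, 0.0, 0.25, 0.75],
        resistance=[1.0, 0.0, 1.0],
        respiration=[0.1, 0.9, 0.0],
        locomotion=[0.4, 0.25, 0.2, 0.15, 0.0],
        diet=[1, 1, 1, 0, 1, 1, 0],
        thermal=[0.1, 0.25, 0.65],
    ),
    "multivoltine_stenotherm": dict(
        body_size=[0.2, 0.7, 0.1, 0.0],
        voltinism=[0.0, 0.2, 0.8],
        reproduction=[0.0, 0.5, 0.5, 0.0],
        dispersal=[0.0, 0.0, 0.5, 0.5],
        resistance=[0.0, 0.0, 0.0],
        respiration=[0.8, 0.2, 0.0],
        locomotion=[0.1, 0.15, 0.05, 0.05, 0.65],
        diet=[0, 1, 0, 0, 0, 1, 0],
        thermal=[0.7, 0.2, 0.1],
    ),
}

#: The single trait with the largest affinity margin per archetype.
DEFINING_TRAITS: dict[str, tuple[str, str]] = {
    "very_large_crawler": ("body_size", "vlarge"),
    "tegument_aquatic_disperser": ("reproduction", "asexual"),
    "spiracle_breather": ("respiration", "spiracle"),
    "small_eurythermic_generalist": ("reproduction", "ovoviviparous"),
    "multivoltine_stenotherm": ("locomotion", "attached"),
}

#: Default abundance responses per archetype: early population collapse of
#: poorly dispersing tegument-breathers, late irruptions of aerial small
#: taxa, gradual decline of large crawlers, and an indifferent group.
DEFAULT_RESPONSES: dict[str, ResponseSpec] = {
    "very_large_crawler": ResponseSpec("linear_down"),
    "tegument_aquatic_disperser": ResponseSpec("threshold_down", breakpoint=0.3, steepness=4.0),
    "spiracle_breather": ResponseSpec("threshold_up", breakpoint=0.6, steepness=4.0),
    "small_eurythermic_generalist": ResponseSpec("threshold_up", breakpoint=0.7, steepness=4.0),
    "multivoltine_stenotherm": ResponseSpec("null"),
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic mesocosm experiment."""

    n_channels: int = 21
    n_genera: int = 45
    seed: int = 0
    stressor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRESSOR_RANGES)
    )
    #: log-scale sd of the multiplicative log-normal stressor noise
    #: (approximately the coefficient of variation).
    stressor_noise_sd: float = 0.05
    #: Dirichlet jitter of trait profiles within an archetype; 0 = exact
    #: archetype profiles, larger = more within-group spread.
    trait_jitter: float = 0.07
    response_specs: dict[str, ResponseSpec] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSES)
    )
    #: expected peak density, individuals per m^2.
    abundance_scale: float = 500.0
    #: 'poisson', 'negative_binomial' or 'none' (noise-free expected values).
    noise_model: str = "poisson"
    nb_dispersion: float = 5.0
    #: specimens measured per genus for the empirical size classes.
    n_length_measurements: int = 30

    def __post_init__(self):
        if self.n_channels < 4:
            raise ValueError("a gradient design needs at least 4 channels")
        if self.n_genera < len(ARCHETYPES):
            raise ValueError("n_genera must cover every archetype at least once")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for name, (lo, hi) in self.stressor_ranges.items():
            if lo == hi:
                raise ValueError(f"degenerate range for stressor {name!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named random stream."""
        key = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


def latent_gradient(n_channels: int) -> np.ndarray:
    """Latent drought position of each channel, uniform on [0, 1]."""
    return np.linspace(0.0, 1.0, n_channels)


# ---------------------------------------------------------------------------
# Stressor table
# ---------------------------------------------------------------------------


def generate_stressor_table(config: GeneratorConfig) -> pd.DataFrame:
    """Channel x stressor table along the latent gradient.

    Each stressor interpolates linearly between its configured endpoints
    (wetted area, volume and flow decrease with the gradient; temperature
    range increases) and is perturbed by multiplicative log-normal noise,
    preserving positivity.
    """
    g = latent_gradient(config.n_channels)
    rng = config.rng("stressors")
    cols = {}
    for name in STRESSORS:
        benign, severe = config.stressor_ranges[name]
        clean = benign + (severe - benign) * g
        noise = (
            np.exp(rng.normal(0.0, config.stressor_noise_sd, config.n_channels))
            if config.stressor_noise_sd > 0
            else 1.0
        )
        cols[name] = clean * noise
    table = pd.DataFrame(cols, index=pd.RangeIndex(config.n_channels, name="channel"))
    return table


# ---------------------------------------------------------------------------
# Trait matrix
# ---------------------------------------------------------------------------


def generate_trait_matrix(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Genus x raw-trait fuzzy matrix drawn from the archetype library.

    Genera are assigned to archetypes round-robin; within each grouping
    feature the genus's affinities are a Dirichlet draw concentrated on the
    archetype profile (concentration 1/``trait_jitter``). All-zero blocks
    (e.g. no resistance strategy) stay exactly zero.

    Returns the matrix and a genus -> archetype label Series (the truth).
    """
    rng = config.rng("traits")
    names = list(ARCHETYPES)
    genera = [f"genus_{i:03d}" for i in range(config.n_genera)]
    labels = pd.Series(
        [names[i % len(names)] for i in range(config.n_genera)],
        index=genera,
        name="archetype",
    )
    rows = []
    for genus in genera:
        arch = ARCHETYPES[labels[genus]]
        row = []
        for feature, traits in RAW_SCHEMA.items():
            base = np.asarray(arch[feature], dtype=float)
            if base.sum() == 0:
                row.extend(np.zeros(len(traits)))
                continue
            p = base / base.sum()
            if config.trait_jitter <= 0:
                row.extend(p)
            else:
                # jitter only within the support: absent trait states stay
                # exactly zero so count-based condensation (diet, resistance)
                # keeps its semantics.
                values = np.zeros_like(p)
                support = p > 0
                if support.sum() == 1:
                    values[support] = 1.0
                else:
                    alpha = p[support] / config.trait_jitter
                    values[support] = rng.dirichlet(alpha)
                row.extend(values)
        rows.append(row)
    matrix = pd.DataFrame(rows, index=genera, columns=schema_columns(RAW_SCHEMA))
    matrix.index.name = "genus"
    return matrix, labels


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------


def logistic_rate_for_max_slope(max_slope: float, breakpoint: float) -> float:
    """Logistic rate r such that the curve rescaled over [0, 1] has the
    requested maximum slope.

    The raw logistic sigma(r (g - b)) restricted to g in [0, 1] spans less
    than (0, 1); after min-max rescaling its maximum slope is
    (r / 4) / (sigma(r (1 - b)) - sigma(-r b)). Solved for r by bisection.
    """
    if max_slope <= 1.0:
        raise ValueError("a [0,1]-spanning curve cannot have max slope <= 1")

    def gap(r):
        span = expit(r * (1 - breakpoint)) - expit(-r * breakpoint)
        return (r / 4.0) / span - max_slope

    return brentq(gap, 1e-9, 5000.0)


def response_curve(spec: ResponseSpec, g: np.ndarray) -> np.ndarray:
    """Noiseless response shape on [0, 1], evaluated at gradient positions."""
    g = np.asarray(g, dtype=float)
    if spec.shape == "null":
        return np.full_like(g, 0.5)
    if spec.shape == "linear_up":
        return g.copy()
    if spec.shape == "linear_down":
        return 1.0 - g
    r = logistic_rate_for_max_slope(spec.steepness, spec.breakpoint)
    raw = expit(r * (g - spec.breakpoint))
    lo = expit(-r * spec.breakpoint)
    hi = expit(r * (1 - spec.breakpoint))
    curve = (raw - lo) / (hi - lo)
    if spec.shape == "threshold_down":
        curve = 1.0 - curve
    return curve


def analytic_threshold_zone(spec: ResponseSpec) -> tuple[float, float] | None:
    """Gradient interval where the noiseless rescaled curve has |slope| > 1.

    This is the estimand of derivative-based zone detection. Linear shapes
    sit exactly on the knife edge (slope identically 1) and return None, as
    do null shapes.
    """
    if not spec.shape.startswith("threshold"):
        return None
    b = spec.breakpoint
    r = logistic_rate_for_max_slope(spec.steepness, b)
    span = expit(r * (1 - b)) - expit(-r * b)
    c = span / r  # |slope| > 1  <=>  sigma (1 - sigma) > c
    if c >= 0.25:
        return None
    s1 = (1 - np.sqrt(1 - 4 * c)) / 2
    g1 = b + np.log(s1 / (1 - s1)) / r
    g2 = b - np.log(s1 / (1 - s1)) / r
    return (max(g1, 0.0), min(g2, 1.0))


def generate_response_series(
    spec: ResponseSpec,
    n_channels: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-scale response with additive Gaussian noise (method studies).

    Used to study the threshold detector under controlled conditions: the
    noiseless curve spans [0, 1] by construction and Gaussian noise with
    standard deviation ``noise_sd`` is added per channel.
    """
    g = latent_gradient(n_channels)
    return response_curve(spec, g) + rng.normal(0.0, noise_sd, n_channels)


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------


def generate_abundances(
    env: pd.DataFrame,
    traits: pd.DataFrame,
    labels: pd.Series,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Channel x genus abundance matrix with per-genus truth records.

    The expected density of a genus is its archetype's response curve
    evaluated at the channel's latent gradient, scaled so that the response
    ranges over [baseline, baseline + effect] x ``abundance_scale``
    (baseline fraction 0.1). Counts are then drawn from the configured
    noise model; with ``noise_model='none'`` the exact expectations are
    returned (useful for shape checks).
    """
    if set(traits.index) != set(labels.index):
        raise KeyError("trait matrix and archetype labels disagree on genera")
    g = latent_gradient(config.n_channels)
    rng = config.rng("abundance")
    dens = {}
    records = []
    for genus in traits.index:
        arch = labels[genus]
        spec = config.response_specs[arch]
        curve = response_curve(spec, g)
        mu = config.abundance_scale * (0.1 + 0.9 * spec.effect_size * curve)
        if config.noise_model == "poisson":
            counts = rng.poisson(mu).astype(float)
        elif config.noise_model == "negative_binomial":
            k = config.nb_dispersion
            counts = rng.negative_binomial(k, k / (k + mu)).astype(float)
        else:
            counts = mu
        dens[genus] = counts
        records.append(
            TruthRecord(
                response_id=genus,
                archetype=arch,
                shape=spec.shape,
                breakpoint=spec.breakpoint,
                analytic_zone=analytic_threshold_zone(spec),
            )
        )
    abundance = pd.DataFrame(dens, index=pd.RangeIndex(config.n_channels, name="channel"))
    return abundance, records


# ---------------------------------------------------------------------------
# Allometry and length measurements
# ---------------------------------------------------------------------------

_SIZE_MASS_RANGES = ((0.01, 0.1), (0.1, 1.0), (1.0, 2.0), (2.0, 10.0))


def generate_allometry(traits: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Per-genus length-mass regression coefficients (m = a L^b, mg/mm)."""
    rng = config.rng("allometry")
    n = len(traits.index)
    a = np.exp(rng.uniform(np.log(0.002), np.log(0.05), n))
    b = rng.uniform(2.2, 3.0, n)
    table = pd.DataFrame({"a": a, "b": b}, index=traits.index)
    table.index.name = "genus"
    return table


def generate_lengths(
    traits: pd.DataFrame,
    allometry: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Specimen body lengths consistent with each genus's size-class mix.

    Target masses are sampled per genus from its (normalized) body-size
    affinities - log-uniform within each mass class - and inverted through
    the genus's allometry to lengths in mm.
    """
    rng = config.rng("lengths")
    size_cols = [("body_size", t) for t in ("small", "medium", "large", "vlarge")]
    rows = []
    for genus in traits.index:
        p = traits.loc[genus, size_cols].to_numpy(dtype=float)
        p = p / p.sum()
        classes = rng.choice(4, size=config.n_length_measurements, p=p)
        lo = np.array([_SIZE_MASS_RANGES[c][0] for c in classes])
        hi = np.array([_SIZE_MASS_RANGES[c][1] for c in classes])
        masses = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        a = float(allometry.loc[genus, "a"])
        b = float(allometry.loc[genus, "b"])
        lengths = (masses / a) ** (1.0 / b)
        rows.extend((genus, float(x)) for x in lengths)
    return pd.DataFrame(rows, columns=["genus", "length_mm"])


# ---------------------------------------------------------------------------
# Dataset bundle and file output
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """All four input tables of a synthetic experiment plus ground truth."""

    env: pd.DataFrame
    traits: pd.DataFrame
    abundance: pd.DataFrame
    allometry: pd.DataFrame
    lengths: pd.DataFrame
    archetype_labels: pd.Series
    truth: list[TruthRecord]
    config: GeneratorConfig


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate the full set of input tables for one synthetic experiment."""
    config = config or GeneratorConfig()
    env = generate_stressor_table(config)
    traits, labels = generate_trait_matrix(config)
    abundance, truth = generate_abundances(env, traits, labels, config)
    allometry = generate_allometry(traits, config)
    lengths = generate_lengths(traits, allometry, config)
    return SyntheticDataset(env, traits, abundance, allometry, lengths, labels, truth, config)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the four input tables as tab-delimited text.

    The trait matrix uses a two-row header (grouping feature, trait).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.env.to_csv(outdir / "environment.tsv", sep="\t")
    ds.traits.to_csv(outdir / "traits.tsv", sep="\t")
    ds.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
    ds.allometry.to_csv(outdir / "allometry.tsv", sep="\t")
    ds.lengths.to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    ds.archetype_labels.to_csv(outdir / "archetypes.tsv", sep="\t")


def read_trait_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genus x (feature, trait) matrix written by :func:`write_dataset`."""
    return pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
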
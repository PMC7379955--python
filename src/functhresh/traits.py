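"""Fuzzy trait profiles and community-weighted trait occurrences.

Benthic macroinvertebrate traits are fuzzy-coded: each genus carries a
vector of nonnegative affinities to the modalities ("traits") of a set of
biological "grouping features" (body size, voltinism, reproduction, ...).
This module normalizes raw affinity tables so that every grouping feature
carries equal weight, condenses dietary breadth and drought-resistance
strategies into single scores, rebuilds body-size classes from measured
specimens via length-mass allometry, and aggregates genus-level profiles
into abundance-weighted community trait profiles per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Trait schema
# ---------------------------------------------------------------------------

#: Raw (database-style) schema: grouping feature -> trait modalities.
#: Diet is coded over seven food types and resistance over three strategies;
#: both are condensed to two-trait blocks for analysis (see condense_diet,
#: condense_resistance).
RAW_SCHEMA: dict[str, tuple[str, ...]] = {
    "body_size": ("small", "medium", "large", "vlarge"),
    "voltinism": ("semivoltine", "univoltine", "multivoltine"),
    "reproduction": ("ovoviviparous", "isolated_eggs", "clutches", "asexual"),
    "dispersal": ("aquatic_passive", "aquatic_active", "aerial_passive", "aerial_active"),
    "resistance": ("eggs_statoblasts", "cocoons_housings", "diapause"),
    "respiration": ("tegument", "gill", "spiracle"),
    "locomotion": ("swimming", "crawling", "burrowing", "interstitial", "attached"),
    "diet": (
        "microorganisms",
        "fine_om",
        "coarse_om",
        "algae",
        "plants",
        "dead_invertebrates",
        "live_invertebrates",
    ),
    "thermal": ("cold", "warm", "eurythermic"),
}

#: Analysis schema after condensation: 9 grouping features, 30 traits.
ANALYSIS_SCHEMA: dict[str, tuple[str, ...]] = {
    "body_size": ("small", "medium", "large", "vlarge"),
    "voltinism": ("semivoltine", "univoltine", "multivoltine"),
    "reproduction": ("ovoviviparous", "isolated_eggs", "clutches", "asexual"),
    "dispersal": ("aquatic_passive", "aquatic_active", "aerial_passive", "aerial_active"),
    "resistance": ("resistant", "susceptible"),
    "respiration": ("tegument", "gill", "spiracle"),
    "locomotion": ("swimming", "crawling", "burrowing", "interstitial", "attached"),
    "diet": ("generalist", "specialist"),
    "thermal": ("cold", "warm", "eurythermic"),
}

#: The 16 individual traits analysed against the drought gradient, with the
#: predicted direction of change under intensifying drought (+1 increase,
#: -1 decrease).
A_PRIORI_TRAITS: dict[tuple[str, str], int] = {
    ("body_size", "small"): +1,
    ("body_size", "medium"): -1,
    ("body_size", "large"): -1,
    ("body_size", "vlarge"): -1,
    ("voltinism", "multivoltine"): +1,
    ("reproduction", "ovoviviparous"): +1,
    ("resistance", "resistant"): +1,
    ("dispersal", "aerial_active"): +1,
    ("dispersal", "aquatic_active"): -1,
    ("locomotion", "crawling"): -1,
    ("locomotion", "burrowing"): +1,
    ("respiration", "tegument"): -1,
    ("respiration", "spiracle"): +1,
    ("diet", "generalist"): +1,
    ("thermal", "cold"): -1,
    ("thermal", "eurythermic"): +1,
}

#: Body-mass class bounds in mg dry mass. Half-open intervals [lo, hi);
#: the largest class is (2, inf).
SIZE_CLASS_BOUNDS: tuple[float, ...] = (0.1, 1.0, 2.0)
SIZE_CLASS_NAMES: tuple[str, ...] = ("small", "medium", "large", "vlarge")

N_FOOD_TYPES = len(RAW_SCHEMA["diet"])
N_RESISTANCE_STRATEGIES = len(RAW_SCHEMA["resistance"])


def schema_columns(schema: dict[str, tuple[str, ...]]) -> pd.MultiIndex:
    """(feature, trait) MultiIndex for a trait table laid out per *schema*."""
    pairs = [(f, t) for f, traits in schema.items() for t in traits]
    return pd.MultiIndex.from_tuples(pairs, names=["feature", "trait"])


def _iter_blocks(columns: pd.MultiIndex):
    for feature in columns.get_level_values(0).unique():
        yield feature, [c for c in columns if c[0] == feature]


# ---------------------------------------------------------------------------
# Normalization and condensation
# ---------------------------------------------------------------------------


def normalize_traits(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Normalize fuzzy affinities to sum to 1 within each grouping feature.

    Equal weighting of grouping features requires each (genus, feature)
    block to sum to one. Blocks that are entirely zero cannot be normalized;
    they are left as zeros and reported.

    Parameters
    ----------
    raw : DataFrame
        Genus x (feature, trait) affinity matrix, nonnegative.

    Returns
    -------
    (normalized, flagged)
        ``flagged`` lists (genus, feature) pairs whose block was all-zero.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("trait affinities must be nonnegative")
    out = raw.astype(float).copy()
    flagged: list[tuple[str, str]] = []
    for feature, cols in _iter_blocks(raw.columns):
        block = out[cols]
        sums = block.sum(axis=1)
        zero = sums == 0
        flagged.extend((g, feature) for g in out.index[zero])
        nz = ~zero
        out.loc[nz, cols] = block.loc[nz].div(sums[nz], axis=0)
    return out, flagged


def condense_diet(food_affinities: pd.DataFrame, min_affinity: float = 0.0) -> pd.DataFrame:
    """Condense seven food-type affinities into generalist/specialist scores.

    The generalist score of a genus is the number of food types it consumes
    (affinity strictly above ``min_affinity``) out of seven, standardized to
    [0, 1]; the specialist score is its complement.

    Returns a DataFrame indexed like the input with columns
    ``generalist``, ``specialist`` and ``n_food_types``; genera consuming
    no food type at all keep generalist 0 (and are detectable via
    ``n_food_types == 0``).
    """
    if food_affinities.shape[1] != N_FOOD_TYPES:
        raise ValueError(
            f"expected {N_FOOD_TYPES} food-type columns, got {food_affinities.shape[1]}"
        )
    counts = (food_affinities > min_affinity).sum(axis=1)
    gen = counts / N_FOOD_TYPES
    return pd.DataFrame(
        {"generalist": gen, "specialist": 1.0 - gen, "n_food_types": counts},
        index=food_affinities.index,
    )


def condense_resistance(
    strategy_affinities: pd.DataFrame, min_affinity: float = 0.0
) -> pd.DataFrame:
    """Condense three resistance strategies into resistant/susceptible scores.

    Analogous to :func:`condense_diet`: the resistant score counts displayed
    strategies (resistant eggs/statoblasts, cocoons/housings, diapause) out
    of three; susceptible is one minus the standardized count.
    """
    if strategy_affinities.shape[1] != N_RESISTANCE_STRATEGIES:
        raise ValueError(
            f"expected {N_RESISTANCE_STRATEGIES} strategy columns, "
            f"got {strategy_affinities.shape[1]}"
        )
    counts = (strategy_affinities > min_affinity).sum(axis=1)
    res = counts / N_RESISTANCE_STRATEGIES
    return pd.DataFrame(
        {"resistant": res, "susceptible": 1.0 - res, "n_strategies": counts},
        index=strategy_affinities.index,
    )


def mass_from_length(length_mm, a: float, b: float):
    """Dry mass (mg) from body length (mm) via the power law ``m = a * L**b``."""
    if a <= 0:
        raise ValueError("allometry coefficient a must be positive")
    return a * np.asarray(length_mm, dtype=float) ** b


def assign_size_classes(
    lengths: pd.DataFrame,
    allometry: pd.DataFrame,
) -> pd.DataFrame:
    """Empirical body-size-class affinities from measured specimen lengths.

    Each measured individual's length (mm) is converted to dry mass (mg)
    with its genus's length-mass regression, masses are pooled across
    channels, and the size-class affinity of a genus is the proportion of
    its individuals falling in each mass class (small < 0.1 mg <= medium
    < 1 mg <= large < 2 mg <= vlarge).

    Parameters
    ----------
    lengths : DataFrame
        Long format with columns ``genus`` and ``length_mm``.
    allometry : DataFrame
        Indexed by genus with columns ``a`` and ``b``.

    Returns
    -------
    DataFrame
        Genus x size-class proportions (rows sum to 1).
    """
    missing = set(lengths["genus"]) - set(allometry.index)
    if missing:
        raise KeyError(f"no allometry coefficients for genera: {sorted(missing)}")
    rows = {}
    for genus, grp in lengths.groupby("genus", sort=True):
        a = float(allometry.loc[genus, "a"])
        b = float(allometry.loc[genus, "b"])
        masses = mass_from_length(grp["length_mm"].to_numpy(), a, b)
        idx = np.searchsorted(SIZE_CLASS_BOUNDS, masses, side="right")
        props = np.bincount(idx, minlength=len(SIZE_CLASS_NAMES)) / len(masses)
        rows[genus] = props
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SIZE_CLASS_NAMES))


def build_analysis_matrix(
    raw: pd.DataFrame,
    size_classes: pd.DataFrame | None = None,
    min_affinity: float = 0.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Raw fuzzy table -> normalized 30-trait analysis matrix.

    Normalizes every raw block, condenses diet and resistance to their
    two-trait forms, and, when measured ``size_classes`` are supplied,
    replaces the database-derived body-size block with the empirical one.

    Returns the analysis matrix (columns per :data:`ANALYSIS_SCHEMA`) and
    the list of all-zero (genus, feature) blocks flagged by normalization.
    """
    normalized, flagged = normalize_traits(raw)
    pieces = []
    for feature, traits in ANALYSIS_SCHEMA.items():
        if feature == "diet":
            block = condense_diet(raw[["diet"]].droplevel(0, axis=1), min_affinity)
            block = block[["generalist", "specialist"]]
        elif feature == "resistance":
            block = condense_resistance(
                raw[["resistance"]].droplevel(0, axis=1), min_affinity
            )
            block = block[["resistant", "susceptible"]]
        elif feature == "body_size" and size_classes is not None:
            block = size_classes.reindex(normalized.index)
            if block.isna().any().any():
                raise KeyError("size_classes missing genera present in trait matrix")
        else:
            block = normalized[[feature]].droplevel(0, axis=1)[list(traits)]
        block = block.copy()
        block.columns = pd.MultiIndex.from_tuples(
            [(feature, t) for t in traits], names=["feature", "trait"]
        )
        pieces.append(block)
    return pd.concat(pieces, axis=1), flagged


# ---------------------------------------------------------------------------
# Community trait profiles
# ---------------------------------------------------------------------------


def community_trait_profile(
    traits: pd.DataFrame,
    abundance: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Abundance-weighted community trait profile per channel.

    The trait-by-genus matrix is weighted by ln(n + 1)-transformed genus
    densities and summed over genera for each channel; the result is
    re-standardized within each grouping feature to sum to 1, yielding
    relative trait occurrences.

    Parameters
    ----------
    traits : DataFrame
        Normalized genus x (feature, trait) matrix.
    abundance : DataFrame
        Channel x genus densities (individuals per m^2).

    Returns
    -------
    (profile, empty_channels)
        ``profile`` is channel x (feature, trait); channels whose community
        is entirely absent are excluded and listed in ``empty_channels``.
    """
    genera = list(traits.index)
    if set(genera) != set(abundance.columns):
        raise KeyError("genus sets of trait matrix and abundance matrix differ")
    dens = abundance[genera].to_numpy(dtype=float)
    if (dens < 0).any():
        raise ValueError("densities must be nonnegative")
    weights = np.log1p(dens)
    raw_profile = weights @ traits.to_numpy(dtype=float)
    profile = pd.DataFrame(raw_profile, index=abundance.index, columns=traits.columns)

    empty = list(abundance.index[dens.sum(axis=1) == 0])
    profile = profile.drop(index=empty)
    for _, cols in _iter_blocks(profile.columns):
        block = profile[cols]
        sums = block.sum(axis=1)
        nz = sums > 0
        profile.loc[nz, cols] = block.loc[nz].div(sums[nz], axis=0)
    return profile, empty
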
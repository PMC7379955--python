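"""Seeded simulation studies quantifying method performance.

Each study generates data with known truth from the synthetic module, runs
the corresponding part of the analysis at the package defaults, and returns
summary rates. The scenarios are the package's standard study conditions:

* Breakpoint recovery: 21 channels, logistic responses with maximum
  rescaled slope 3 centred at gradient positions 0.3 / 0.5 / 0.7,
  Gaussian noise sd 0.05.
* Response-type discrimination: a three-response family per replicate -
  a linear trend whose rescaled slope sits below 1 because residual noise
  (sd 0.15) inflates the observed range, a steep logistic (maximum rescaled
  slope 4, sd 0.08) and a null response (sd 0.10) - with
  Benjamini-Hochberg control within the family.
* Type-I error: families of pure-noise responses.
* Trait-profile-group recovery: the five-archetype community at default
  jitter (between-group Gower distance >= 3x within-group spread).
* Taxonomy consistency: a 16-response family shaped like the trait
  response taxonomy of the mesocosm study it emulates - 5 linear,
  7 threshold responses with breakpoints spread over [0.64, 0.91] and
  4 null responses.

The detected breakpoint estimates the lower bound of the |slope| > 1 zone
of the underlying curve (the analytic zone), not the logistic centre, so
breakpoint error is measured against the analytic zone bound while zone
coverage is assessed for the centre (the generator's nominal breakpoint).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .synthetic import (
    DEFINING_TRAITS,
    GeneratorConfig,
    ResponseSpec,
    analytic_threshold_zone,
    generate_response_series,
    generate_trait_matrix,
    latent_gradient,
)
from .thresholds import analyze_family, bh_adjust, detect_zones, derivative_profile, fit_gam, rescale_unit
from .tpg import gini_importance, gower_matrix, select_k_by_anosim
from .traits import build_analysis_matrix

N_CHANNELS = 21
RECOVERY_BREAKPOINTS = (0.3, 0.5, 0.7)
RECOVERY_SLOPE = 3.0
RECOVERY_NOISE_SD = 0.05
LINEAR_NOISE_SD = 0.15
STEEP_SLOPE = 4.0
STEEP_NOISE_SD = 0.08
NULL_NOISE_SD = 0.10
TAXONOMY_BREAKPOINTS = tuple(np.round(np.linspace(0.64, 0.91, 7), 4))


def _rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, rep]))


def _fit_and_zones(y: np.ndarray):
    di = latent_gradient(len(y))
    fit = fit_gam(di, rescale_unit(y))
    grid, deriv = derivative_profile(fit)
    zones, breakpoint, multiple = detect_zones(grid, deriv)
    return fit, zones, breakpoint


def breakpoint_recovery_study(seed: int, n_reps: int = 100) -> dict:
    """Recover logistic breakpoints under the standard recovery scenario.

    Returns the fraction of significant fits whose dominant threshold zone
    contains the true logistic centre, and the mean absolute difference
    between the detected breakpoint (zone lower bound) and the analytic
    zone lower bound of the noiseless curve.
    """
    covered = significant = with_zone = 0
    errors = []
    for rep in range(n_reps):
        bp = RECOVERY_BREAKPOINTS[rep % len(RECOVERY_BREAKPOINTS)]
        spec = ResponseSpec("threshold_up", breakpoint=bp, steepness=RECOVERY_SLOPE)
        y = generate_response_series(spec, N_CHANNELS, RECOVERY_NOISE_SD, _rng(seed, rep))
        fit, zones, detected = _fit_and_zones(y)
        if fit.p_value >= 0.05:
            continue
        significant += 1
        if not zones:
            continue
        with_zone += 1
        dominant = next(z for z in zones if z[0] == detected)
        if dominant[0] - 1e-12 <= bp <= dominant[1] + 1e-12:
            covered += 1
        errors.append(abs(detected - analytic_threshold_zone(spec)[0]))
    return {
        "n_significant": significant,
        "n_with_zone": with_zone,
        "coverage_rate": covered / significant if significant else float("nan"),
        "mean_abs_breakpoint_error": float(np.mean(errors)) if errors else float("nan"),
    }


def discrimination_study(seed: int, n_reps: int = 100) -> dict:
    """Classify one linear, one steep-threshold and one null response per
    replicate; report the per-type correct-classification rates."""
    hits = {"L": 0, "T": 0, "N": 0}
    steep = ResponseSpec("threshold_up", breakpoint=0.5, steepness=STEEP_SLOPE)
    di = latent_gradient(N_CHANNELS)
    for rep in range(n_reps):
        rng = _rng(seed, rep)
        linear_shape = "linear_up" if rep % 2 == 0 else "linear_down"
        family = pd.DataFrame(
            {
                "L": generate_response_series(
                    ResponseSpec(linear_shape), N_CHANNELS, LINEAR_NOISE_SD, rng
                ),
                "T": generate_response_series(steep, N_CHANNELS, STEEP_NOISE_SD, rng),
                "N": generate_response_series(
                    ResponseSpec("null"), N_CHANNELS, NULL_NOISE_SD, rng
                ),
            }
        )
        results, _ = analyze_family(di, family)
        for res in results:
            if res.response_type == res.response_id:
                hits[res.response_id] += 1
    return {kind: hits[kind] / n_reps for kind in hits}


def type_i_study(seed: int, n_reps: int = 200, family_size: int = 5) -> dict:
    """Fraction of pure-noise responses declared significant (non-N) after
    within-family Benjamini-Hochberg control at alpha 0.05."""
    di = latent_gradient(N_CHANNELS)
    false_positives = total = 0
    for rep in range(n_reps):
        rng = _rng(seed, rep)
        p_values = []
        for _ in range(family_size):
            y = generate_response_series(
                ResponseSpec("null"), N_CHANNELS, NULL_NOISE_SD, rng
            )
            p_values.append(fit_gam(di, rescale_unit(y)).p_value)
        adjusted = bh_adjust(p_values)
        false_positives += int((adjusted < 0.05).sum())
        total += family_size
    rate = false_positives / total
    se = float(np.sqrt(0.05 * 0.95 / total))
    return {"non_n_rate": rate, "bound": 0.05 + 2 * se, "n_tests": total}


def tpg_recovery_study(seed: int, n_reps: int = 50, n_trees: int = 500) -> dict:
    """Recover the five trait archetypes from jittered communities.

    Reports how often cluster-number selection returns the true number of
    groups with adjusted Rand >= 0.9, the between/within Gower distance
    ratio of the scenario, and how often each archetype's defining trait
    attains the top per-group Gini importance.
    """
    k_correct = ari_ok = 0
    gini_top = gini_total = 0
    ratios = []
    for rep in range(n_reps):
        config = GeneratorConfig(seed=int(_rng(seed, rep).integers(2**31)))
        traits, labels = generate_trait_matrix(config)
        matrix, _ = build_analysis_matrix(traits)
        distance = gower_matrix(matrix)
        lab = labels.to_numpy()
        d = distance.to_numpy()
        iu = np.triu_indices(len(d), 1)
        within = lab[iu[0]] == lab[iu[1]]
        ratios.append(d[iu][~within].mean() / d[iu][within].mean())
        assignment = select_k_by_anosim(distance)
        if assignment.k == 5:
            k_correct += 1
            if adjusted_rand_score(lab, assignment.labels.to_numpy()) >= 0.9:
                ari_ok += 1
        gini = gini_importance(matrix, labels, n_trees=n_trees, seed=config.seed)
        for group, sub in gini.groupby("group"):
            best = sub.loc[sub["gini"].idxmax()]
            gini_total += 1
            gini_top += (best["feature"], best["trait"]) == DEFINING_TRAITS[group]
    return {
        "k_correct_rate": k_correct / n_reps,
        "recovery_rate": ari_ok / n_reps,
        "min_separation_ratio": float(min(ratios)),
        "gini_top_rate": gini_top / gini_total,
    }


def taxonomy_consistency_study(seed: int, n_reps: int = 20) -> dict:
    """Type assignments on a 16-response family mirroring the observed
    trait-response taxonomy (5 L, 7 T with late breakpoints, 4 N).

    Returns the per-replicate match counts and their median.
    """
    di = latent_gradient(N_CHANNELS)
    specs: list[tuple[str, ResponseSpec, float]] = []
    for i in range(5):
        shape = "linear_up" if i % 2 == 0 else "linear_down"
        specs.append(("L", ResponseSpec(shape), LINEAR_NOISE_SD))
    for i, bp in enumerate(TAXONOMY_BREAKPOINTS):
        shape = "threshold_up" if i % 2 == 0 else "threshold_down"
        specs.append(
            ("T", ResponseSpec(shape, breakpoint=float(bp), steepness=STEEP_SLOPE),
             STEEP_NOISE_SD)
        )
    for _ in range(4):
        specs.append(("N", ResponseSpec("null"), NULL_NOISE_SD))

    matches = []
    for rep in range(n_reps):
        rng = _rng(seed, rep)
        family = pd.DataFrame(
            {
                f"{kind}_{i}": generate_response_series(spec, N_CHANNELS, sd, rng)
                for i, (kind, spec, sd) in enumerate(specs)
            }
        )
        results, _ = analyze_family(di, family)
        count = sum(r.response_type == r.response_id.split("_")[0] for r in results)
        matches.append(count)
    return {
        "matches": matches,
        "median_matches": float(np.median(matches)),
        "n_responses": len(specs),
    }
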
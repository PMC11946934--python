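"""End-to-end validation study: parameter recovery and interval calibration.

Simulates datasets with the structure the model assumes (5 regions × 5
countries, two observations of roughly 200 deaths per country, all
countries observed), fits the hierarchical model, and measures (a) the
mean absolute error of posterior-median country cause proportions
against the simulated truth and (b) the fraction of true proportions
inside the 80% uncertainty intervals. Because all checks within one
dataset share a single draw of the hierarchy, results are pooled over
independent replicate datasets (two by default, giving 350
country×cause coverage checks); every replicate derives its seeds from
the one master seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .aggregate import aggregate
from .model import ModelConfig, fit
from .simulate import SimConfig, generate, truth_coverage_check


def calibration_scenario(seed: int) -> SimConfig:
    """The recovery-study generating conditions (one replicate)."""
    return SimConfig(
        n_regions=5,
        countries_per_region=5,
        obs_per_country=2,
        deaths_per_obs=(150, 250),
        missing_country_fraction=0.0,
        seed=seed,
    )


def calibration_study(
    seed: int = 1,
    n_datasets: int = 2,
    model_config: Optional[ModelConfig] = None,
) -> dict:
    """Recovery MAE and 80%-UI coverage, pooled over replicate datasets.

    Comparisons are on the non-HIV scale (the scale of the recorded
    truth). Returns pooled ``mae``, ``coverage``, ``n_checks`` and
    per-dataset details.
    """
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    per_dataset = []
    errs: list[float] = []
    hits = 0
    n_checks = 0
    for child in children:
        gseed, mseed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        ds, truth = generate(calibration_scenario(gseed))
        cfg = model_config or ModelConfig()
        cfg = ModelConfig(**{**cfg.__dict__, "seed": mseed})
        ps = fit(ds, cfg)
        agg = aggregate(ps, ds.envelope, window=ds.window, with_hiv=False)
        country_summaries = [s for s in agg.summaries if s.level == "country"]
        abs_err = np.concatenate(
            [
                np.abs(s.prop_median - truth.p_country[truth.countries.index(s.unit)])
                for s in country_summaries
            ]
        )
        cov = truth_coverage_check(truth, country_summaries)["country"]
        per_dataset.append(
            {
                "mae": float(abs_err.mean()),
                "coverage": cov["coverage"],
                "n_checks": cov["n_checks"],
                "converged": ps.converged,
            }
        )
        errs.extend(abs_err)
        hits += round(cov["coverage"] * cov["n_checks"])
        n_checks += cov["n_checks"]
    return {
        "mae": float(np.mean(errs)),
        "coverage": hits / n_checks,
        "n_checks": n_checks,
        "per_dataset": per_dataset,
    }
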
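import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sptraj.pipeline import (RunConfig, multisection_design, run_benchmark,
                             run_pipeline, standard_designs,
                             _default_preprocess)
from sptraj.simulate import SimConfig, simulate

ABLATION_MODES = ("full", "no_spatial_reuse", "no_adaptive_density",
                  "no_embedding")
BENCH_SEEDS = (0, 1, 2, 3, 4)
STABILITY_SEEDS = (5, 6, 7, 8, 9)


@pytest.fixture(scope="session")
def benchmark_table() -> pd.DataFrame:
    """Recovery benchmark shared by the simulation-scale acceptance checks.

    Full model plus the three component ablations on the five standard
    designs at n=500, seeds 0-4, plus five extra full-model bifurcating
    seeds for the stability analysis.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        designs = standard_designs()
        tab = run_benchmark(designs, methods=ABLATION_MODES, seeds=BENCH_SEEDS)
        extra = run_benchmark({"bifurcating": designs["bifurcating"]},
                              methods=("full",), seeds=STABILITY_SEEDS)
    return pd.concat([tab, extra], ignore_index=True)


@pytest.fixture(scope="session")
def sim_bif_small():
    """Small bifurcating dataset for unit-scale pipeline tests."""
    return simulate(SimConfig(n_cells=150, n_genes=60,
                              n_marker_genes_per_branch=6, seed=3))


@pytest.fixture(scope="session")
def ot_bundle_200():
    """Full pipeline on a 200-cell bifurcating dataset."""
    sim = simulate(SimConfig(n_cells=200, seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(
            RunConfig(seed=0, preprocess=_default_preprocess()),
            sim.dataset, {"mode": "by_type", "target_type": "root"})
    return bundle, sim


@pytest.fixture(scope="session")
def radial_run():
    """Full pipeline on the radial outward design (velocity oracle)."""
    sim = simulate(SimConfig(topology="linear", spatial_pattern="radial",
                             n_cells=500, seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(
            RunConfig(seed=0, preprocess=_default_preprocess()),
            sim.dataset, {"mode": "by_type", "target_type": "root"})
    return bundle, sim


@pytest.fixture(scope="session")
def multisection_run():
    """Shared-embedding multi-section inference on the Sim5-like design."""
    from sptraj.multisection import (build_shared_embedding, global_pseudotime,
                                     per_section_inference, split_sections)

    sim = simulate(multisection_design(seed=0))
    sections = split_sections(sim.dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shared = build_shared_embedding(sections, seed=0)
        starts = [{"mode": "by_type", "target_type": "root"}] * len(sections)
        results = per_section_inference(shared, sections, starts)
    labels = np.asarray(sim.dataset.section).astype(str)
    order = sorted(set(labels.tolist()))
    global_tau = global_pseudotime(results)
    return {"sim": sim, "sections": sections, "shared": shared,
            "results": results, "section_order": order,
            "global_tau": global_tau}
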
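"""Shared fixtures: geometry, acquisition, and a seeded reference dataset.

The session-scoped population dataset (400 cells per phenotype, default
generator settings) backs the statistical tests; smaller throwaway
datasets are built inline where cheaper.
"""

from __future__ import annotations

import numpy as np
import pytest

from undulate.channel import ChannelGeometry
from undulate.simulate import (AcquisitionConfig, ArtifactsConfig,
                               CellParams, default_phenotypes,
                               generate_dataset, sample_population,
                               simulate_trajectories)
from undulate.tracking import track_dataset
from undulate.features import (partition_regions, shape_series,
                               extract_features)

REFERENCE_SEED = 20260922


@pytest.fixture(scope="session")
def geometry() -> ChannelGeometry:
    return ChannelGeometry()


@pytest.fixture(scope="session")
def acquisition() -> AcquisitionConfig:
    return AcquisitionConfig()


def make_cell(cell_id=0, phenotype="HL60", radius=6.0, gain=6.0e-5,
              tau=0.042, entry_time=0.0, **kw) -> CellParams:
    return CellParams(cell_id=cell_id, phenotype=phenotype, radius=radius,
                      gain=gain, tau=tau, entry_time=entry_time, **kw)


@pytest.fixture(scope="session")
def reference_truth(geometry, acquisition):
    """True (noise-free) trajectories of the default population.

    300 cells per phenotype; used for simulator-fidelity statistics
    without the cost of rendering.
    """
    pop = sample_population(default_phenotypes(), 300, seed=REFERENCE_SEED)
    trajs = simulate_trajectories(pop, geometry, acquisition)
    return pop, trajs


@pytest.fixture(scope="session")
def reference_dataset(geometry, acquisition):
    """Rendered + tracked + feature-extracted default population.

    400 cells per phenotype with default rendering noise.  Returns a
    dict with the population, kept trajectories, shape series, and the
    feature table used by the classification tests.
    """
    pop = sample_population(default_phenotypes(), 400,
                            seed=REFERENCE_SEED + 1)
    dataset = generate_dataset(pop, geometry, acquisition,
                               ArtifactsConfig(), seed=REFERENCE_SEED + 1)
    kept, discarded = track_dataset(dataset.detections, geometry)
    feats, report = extract_features(kept, geometry, acquisition.pixel_size)
    series = report.kept
    for s in series:
        if s.partition is None:
            partition_regions(s, geometry)
    return {
        "population": pop,
        "dataset_meta": dataset.meta,
        "trajectories": kept,
        "discarded": discarded,
        "series": series,
        "features": feats,
        "filter_report": report,
    }


def features_matrix(feats, names, pair):
    """Binary (X, y) for a phenotype pair from FeatureVector lists."""
    rows, labels = [], []
    for f in feats:
        if f.phenotype in pair:
            rows.append(f.as_array(names))
            labels.append(int(f.phenotype == pair[1]))
    return np.array(rows), np.array(labels)


def gaussian_bayes_oracle(configs_by_name, pair):
    """Likelihood-ratio classifier on the true (gain, tau, radius).

    Treats each phenotype's generative parameters as independent
    normals (truncation at zero is negligible for the default
    configurations) and classifies a cell by the sign of the
    log-likelihood ratio.  Returns a function cell -> predicted label
    (0 = pair[0], 1 = pair[1]).
    """
    a, b = (configs_by_name[p] for p in pair)

    def loglik(cfg, cell):
        out = 0.0
        for value, mean, sd in (
                (cell.gain, cfg.gain_mean, cfg.gain_sd),
                (cell.tau, cfg.tau_mean, cfg.tau_sd),
                (cell.radius, cfg.radius_mean, cfg.radius_sd)):
            out += -0.5 * ((value - mean) / sd) ** 2 - np.log(sd)
        return out

    return lambda cell: int(loglik(b, cell) > loglik(a, cell))
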
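"""Shared fixtures: one mid-sized synthetic study reused across modules."""

from __future__ import annotations

import pytest

from splicehotspot.classifier import ClassifierConfig, train
from splicehotspot.features import build_feature_table
from splicehotspot.junctions import (
    collapse_replicates,
    filter_annotated_junctions,
    usage_table,
)
from splicehotspot.mapsy import mapsy_table
from splicehotspot.synthetic import (
    SimulationConfig,
    exon_frame,
    simulate_annotation,
    simulate_hexamer_table,
    simulate_junction_samples,
    simulate_mapsy,
    simulate_rbp_data,
)

# 300 trees keep every GBM fit a few seconds while leaving the planted
# signal easily recoverable; the library default stays at 1000
TEST_TREES = 300


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7, n_genes=40)


@pytest.fixture(scope="session")
def study(config):
    """(annotation, genome, ground truth) for the default study."""
    return simulate_annotation(config)


@pytest.fixture(scope="session")
def annotation(study):
    return study[0]


@pytest.fixture(scope="session")
def genome(study):
    return study[1]


@pytest.fixture(scope="session")
def truth(study):
    return study[2]


@pytest.fixture(scope="session")
def exons(truth):
    return exon_frame(truth)


@pytest.fixture(scope="session")
def mapsy_counts(annotation, truth, config, genome):
    return simulate_mapsy(annotation, truth, config, genome)


@pytest.fixture(scope="session")
def mapsy_annotated(mapsy_counts):
    return mapsy_table(mapsy_counts)


@pytest.fixture(scope="session")
def junction_samples(annotation, truth, config):
    return simulate_junction_samples(annotation, truth, config)


@pytest.fixture(scope="session")
def usage_cell1(annotation, junction_samples):
    collapsed = collapse_replicates([
        filter_annotated_junctions(t, annotation)
        for t in junction_samples["cell1"].values()
    ])
    return usage_table(annotation, collapsed)


@pytest.fixture(scope="session")
def hexamers(config):
    return simulate_hexamer_table(config)


@pytest.fixture(scope="session")
def rbp_data(annotation, truth, config):
    return simulate_rbp_data(annotation, truth, config)


@pytest.fixture(scope="session")
def feature_table(mapsy_counts, exons, annotation, genome, hexamers,
                  usage_cell1):
    return build_feature_table(
        mapsy_counts, exons, annotation, genome, hexamers, usage=usage_cell1
    )


@pytest.fixture(scope="session")
def labels(mapsy_counts, truth):
    return mapsy_counts["variant_id"].map(truth.variant_disrupting)


@pytest.fixture(scope="session")
def trained_model(feature_table, labels):
    return train(feature_table, labels, ClassifierConfig(n_trees=TEST_TREES,
                                                         seed=0))
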
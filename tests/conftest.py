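"""Shared fixtures: the default synthetic experiment and its pipeline run.

The expensive end-to-end run on the default dataset (~3000 cells, 2000
genes, seed 1) is computed once per session and shared by the recovery
and acceptance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

import trichoflow as tf


@dataclass
class DefaultRun:
    sim: tf.SimulatedExperiment
    config: tf.PipelineConfig
    result: tf.PipelineResult
    truth_idx: np.ndarray  # maps pipeline cells -> rows of sim.counts

    @property
    def truth_type(self) -> np.ndarray:
        return self.sim.truth.type_label[self.truth_idx]

    @property
    def truth_phase(self) -> np.ndarray:
        return self.sim.truth.phase_label[self.truth_idx]

    @property
    def truth_time(self) -> np.ndarray:
        return self.sim.truth.latent_time[self.truth_idx]

    @property
    def truth_branch(self) -> np.ndarray:
        return self.sim.truth.branch[self.truth_idx]

    def majority_type(self, cluster) -> str:
        labels = self.truth_type[self.result.cluster_labels == cluster]
        values, counts = np.unique(labels, return_counts=True)
        return str(values[np.argmax(counts)])


@pytest.fixture(scope="session")
def default_run() -> DefaultRun:
    sim = tf.simulate_experiment(tf.SimConfig(seed=1))
    config = tf.PipelineConfig(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = tf.run_pipeline(
            sim.counts, sim.marker_db, sim.homology,
            sim.truth.phase_genes, config=config,
        )
    barcode_pos = {b: i for i, b in enumerate(sim.counts.barcodes)}
    idx = np.array([barcode_pos[b] for b in result.counts.barcodes])
    return DefaultRun(sim=sim, config=config, result=result, truth_idx=idx)


@pytest.fixture()
def small_sim_config() -> tf.SimConfig:
    return tf.SimConfig(
        n_cells_per_sample=300, n_genes=800, n_ambient_per_sample=100, seed=7
    )


@pytest.fixture()
def tiny_matrix() -> tf.CountMatrix:
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(12, 9))
    return tf.CountMatrix(
        counts=counts,
        barcodes=[f"BC{i:02d}" for i in range(12)],
        genes=[f"g{j}" for j in range(9)],
        sample_labels=["S1"] * 6 + ["S2"] * 6,
    )
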
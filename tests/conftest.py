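"""Shared fixtures: a default synthetic dataset and a full pipeline run.

The heavy fixtures are session-scoped so the end-to-end products
(k-mer vectors, lakd table, clustering) are computed once and shared by
the module and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from kmernet import cli, distance_stats, kmer_core, profiles_clustering
from kmernet.synthetic_data import SyntheticConfig, SyntheticDataset, generate_dataset

CLUSTER_SEED = 1


@dataclass
class PipelineRun:
    """All intermediate products of one full pipeline run."""

    dataset: SyntheticDataset
    sequences: dict
    vectors: dict            # node_id -> KmerVector (k = 4)
    composition: pd.DataFrame
    lakd: pd.DataFrame
    edge_distances: dict
    joint: pd.DataFrame
    degrees_used: list
    clustering: profiles_clustering.ClusteringResult
    cluster_summary: pd.DataFrame

    @property
    def network(self):
        return self.dataset.network


@pytest.fixture(scope="session")
def default_dataset() -> SyntheticDataset:
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def pipeline_run(default_dataset) -> PipelineRun:
    ds = default_dataset
    net = ds.network
    standardized = cli.standardize_nodes(ds.records, ds.config.window)
    sequences, dropped = cli.extract_sequences(ds.genome, standardized)
    assert dropped == 0  # synthetic windows are in bounds by construction
    vectors = cli.build_vectors(sequences, net, k=4)
    composition = cli.build_composition(sequences, net)
    lakd_table = distance_stats.lakd(net, vectors)
    dists = distance_stats.edge_distances(net, vectors)
    vector_list = list(vectors.values())
    prom = profiles_clustering.degree_profiles(vector_list, "promoter", 10)
    enh = profiles_clustering.degree_profiles(vector_list, "enhancer", 10)
    joint, degrees_used = profiles_clustering.joint_profiles(prom, enh)
    clustering = profiles_clustering.cluster_joint_profiles(
        joint, degrees_used, k_max=10, B=50, restarts=10, seed=CLUSTER_SEED,
    )
    summary = profiles_clustering.annotate_clusters(
        joint, clustering.assignments, kmer_core.cpg_kmer_set(4), degrees_used,
    )
    return PipelineRun(
        dataset=ds, sequences=sequences, vectors=vectors,
        composition=composition, lakd=lakd_table, edge_distances=dists,
        joint=joint, degrees_used=degrees_used,
        clustering=clustering, cluster_summary=summary,
    )
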
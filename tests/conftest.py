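import numpy as np
import pytest

import rescon


@pytest.fixture(scope="session")
def subgrouped():
    """Two planted subgroups, 150+150 records, 8 pattern columns each."""
    aln, truth = rescon.make_subgrouped_msa([150, 150], 100, 8, 0.9, seed=11)
    return aln, truth


@pytest.fixture(scope="session")
def small_potts():
    """Small Potts fixture with one strongly coupled pair."""
    aln, truth = rescon.sample_potts(12, 600, [(3, 8)], coupling_strength=3.0, seed=7)
    return aln, truth


@pytest.fixture(scope="session")
def small_potts_scores(small_potts):
    aln, _ = small_potts
    return rescon.dca_scores(aln, max_iter=80)


@pytest.fixture(scope="session")
def toy_cluster_structure():
    """150-residue helix with residues 40..49 planted in a 10 A ball."""
    members = list(range(40, 50))
    model, truth = rescon.make_toy_structure(
        150, "extended_helix", planted_cluster=(members, 10.0), seed=2
    )
    return model, truth


@pytest.fixture(scope="session")
def toy_distance_matrix(toy_cluster_structure):
    model, _ = toy_cluster_structure
    pts = np.vstack([r.coords[0] for r in model.residues])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def make_alignment(rows, query_id=None, structure_ids=()):
    """Build an Alignment from (id, row) pairs."""
    recs = [rescon.Record(i, r) for i, r in rows]
    return rescon.Alignment(
        recs, query_id or rows[0][0], frozenset(structure_ids)
    )
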
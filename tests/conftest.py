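import itertools

import numpy as np
import pandas as pd
import pytest

from regiospec import ExpressionBundle, simulate


@pytest.fixture
def tiny_bundle() -> ExpressionBundle:
    """2 donors x 2 regions, 3 probes / 2 genes; values solvable by hand."""
    samples = ["s1", "s2", "s3", "s4"]
    matrix = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [3.0, 7.0, 2.0],
            "s3": [3.0, 6.0, 2.0],
            "s4": [5.0, 8.0, 2.0],
        },
        index=["p1", "p2", "p3"],
    )[samples]
    probe_annot = pd.Series(["GA", "GA", "GB"], index=matrix.index, name="gene_symbol")
    sample_annot = pd.DataFrame(
        {
            "donor_id": ["d1", "d1", "d2", "d2"],
            "region_name": ["other", "focal", "other", "focal"],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionBundle(matrix, probe_annot, sample_annot)


@pytest.fixture(scope="session")
def default_atlas():
    """One seeded draw of the default synthetic study conditions."""
    cfg = simulate.SyntheticConfig(seed=7)
    bundle, truth = simulate.generate_atlas(cfg)
    collection = simulate.generate_gene_sets(truth, cfg)
    return cfg, bundle, truth, collection


def make_ranking(scores: np.ndarray) -> pd.DataFrame:
    genes = [f"g{i:03d}" for i in range(len(scores))]
    df = pd.DataFrame({"signed_score": np.asarray(scores, float)}, index=genes)
    return df.sort_values("signed_score", ascending=False)


# ---- independent oracles, deliberately naive -----------------------------


def brute_force_auroc(ranking: pd.DataFrame, members) -> float:
    """Pairwise comparison count; ties on score get half credit."""
    scores = ranking["signed_score"]
    member_scores = [scores[g] for g in ranking.index if g in members]
    other_scores = [scores[g] for g in ranking.index if g not in members]
    wins = 0.0
    for m in member_scores:
        for o in other_scores:
            if m > o:
                wins += 1.0
            elif m == o:
                wins += 0.5
    return wins / (len(member_scores) * len(other_scores))


def enumerate_mwu_tail(n_top_positions, n1: int, N: int) -> float:
    """P(U >= observed) by enumerating all placements of n1 members in N slots."""
    obs_u = _u_of_positions(n_top_positions, N)
    count = 0
    total = 0
    for pos in itertools.combinations(range(N), n1):
        total += 1
        if _u_of_positions(pos, N) >= obs_u:
            count += 1
    return count / total


def _u_of_positions(positions, N: int) -> int:
    members = set(positions)
    u = 0
    for m in members:
        for o in range(N):
            if o not in members and m < o:
                u += 1
    return u


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """q_(i) = min_{j>=i} m p_(j)/j, capped at 1, in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank_from_end in range(m, 0, -1):
        idx = order[rank_from_end - 1]
        running = min(running, m * p[idx] / rank_from_end)
        q_sorted[rank_from_end - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
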
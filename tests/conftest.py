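import numpy as np
import pandas as pd
import pytest

from metagrs.genotypes import GenotypeMatrix
from metagrs.sumstats import SumStats


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_sumstats():
    """Five well-behaved variants on one chromosome."""
    df = pd.DataFrame(
        {
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "id": [f"rs{i}" for i in range(1, 6)],
            "ea": ["A", "C", "A", "G", "A"],
            "oa": ["G", "T", "G", "C", "G"],
            "beta": [0.1, -0.2, 0.05, 0.3, 0.0],
            "se": [0.01, 0.02, 0.01, 0.05, 0.02],
            "p": [1e-8, 1e-4, 0.01, 0.04, 0.9],
            "eaf": [0.3, 0.1, 0.25, 0.4, 0.05],
        }
    )
    return SumStats(df, trait="toy")


@pytest.fixture
def tiny_panel():
    """3 samples x 4 variants with hand-set dosages."""
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "id": ["rs1", "rs2", "rs3", "rs4"],
            "ea": ["A", "C", "A", "G"],
            "oa": ["G", "T", "G", "C"],
        }
    )
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [1.0, 0.0, 2.0, 1.0],
            [2.0, 2.0, 0.0, np.nan],
        ]
    )
    return GenotypeMatrix(["A1", "A2", "A3"], variants, dosages)


def bh_oracle(pvalues):
    """Independent step-up computation: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def harrell_c_oracle(entry, exit_, event, score):
    """Exhaustive pair enumeration under left truncation."""
    n = len(score)
    conc = pairs = 0.0
    for i in range(n):
        if not event[i]:
            continue
        t = exit_[i]
        for j in range(n):
            if j == i:
                continue
            if entry[j] < t and (exit_[j] > t or (exit_[j] == t and not event[j])):
                pairs += 1
                if score[i] > score[j]:
                    conc += 1
                elif score[i] == score[j]:
                    conc += 0.5
    if pairs == 0:
        raise ValueError("no comparable pairs")
    return conc / pairs


def greedy_prune_oracle(genotypes, window_kb, r2_max):
    """Plain-python restatement of the greedy left-to-right pruning rule."""
    X = genotypes.dosages.astype(float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        mean = np.nanmean(col) if np.isfinite(col).any() else 0.0
        col[np.isnan(col)] = mean
    v = genotypes.variants
    kept = []
    for j in range(len(v)):
        ok = True
        for k in kept:
            if v["chrom"].iloc[k] != v["chrom"].iloc[j]:
                continue
            if v["pos"].iloc[j] - v["pos"].iloc[k] > window_kb * 1000:
                continue
            a, b = X[:, j], X[:, k]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept
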
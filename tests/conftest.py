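"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from livmet import ColocParams, GenePanel, UNASSIGNED


def brute_close_count(table, source, partner, params=ColocParams()):
    """O(n_A * n_B) reference for the close-interaction count.

    Independent of the k-d tree implementation: plain pairwise distances,
    strict threshold, same-cell exclusion, self-pairing forbidden,
    unassigned transcripts as singleton cells (or dropped).
    """
    df = table.reset_index(drop=True)
    una = df["cell_id"].astype(str) == UNASSIGNED
    if params.unassigned_policy == "drop":
        df = df.loc[~una].reset_index(drop=True)
        una = una[~una].reset_index(drop=True)
    cells = df["cell_id"].astype(str).to_list()
    # singleton policy: give each unassigned row a unique cell label
    cells = [f"__una_{i}" if u else c for i, (c, u) in enumerate(zip(cells, una))]
    src = df.index[df["gene"] == source]
    par = df.index[df["gene"] == partner]
    count = 0
    for i in src:
        hit = False
        for j in par:
            if i == j:
                continue
            d = np.hypot(df.x[i] - df.x[j], df.y[i] - df.y[j])
            if d >= params.radius:
                continue
            if params.same_cell_exclusion and cells[i] == cells[j]:
                continue
            hit = True
            break
        if hit:
            count += 1
    return count


def brute_matrix(table, panel, params=ColocParams()):
    """Brute-force score matrix matching coloc_matrix semantics."""
    g = len(panel)
    values = np.full((g, g), np.nan)
    df = table.reset_index(drop=True)
    if params.unassigned_policy == "drop":
        df = df.loc[df["cell_id"].astype(str) != UNASSIGNED].reset_index(drop=True)
    n = {gene: int((df["gene"] == gene).sum()) for gene in panel.genes}
    for i, a in enumerate(panel.genes):
        for j, b in enumerate(panel.genes):
            denom = n[a] + n[b]
            if denom == 0:
                continue
            values[i, j] = 2.0 * brute_close_count(df, a, b, params) / denom
    if not params.include_diagonal:
        np.fill_diagonal(values, np.nan)
    return values


def random_table(rng, n_genes=4, max_per_gene=60, field=200.0, unassigned_frac=0.0):
    """Random transcript table for oracle-equivalence checks."""
    frames = []
    for k in range(n_genes):
        n = int(rng.integers(0, max_per_gene + 1))
        frames.append(
            pd.DataFrame(
                {
                    "gene": f"g{k}",
                    "x": rng.uniform(0, field, n),
                    "y": rng.uniform(0, field, n),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    pitch = 20.0
    df["cell_id"] = (
        np.floor(df.x / pitch).astype(int).astype(str)
        + "_"
        + np.floor(df.y / pitch).astype(int).astype(str)
    )
    if unassigned_frac > 0 and len(df):
        mask = rng.random(len(df)) < unassigned_frac
        df.loc[mask, "cell_id"] = UNASSIGNED
    return df


@pytest.fixture
def toy_table():
    """The four-transcript worked example: score(A,B) = 0.5 both ways."""
    return pd.DataFrame(
        {
            "gene": ["A", "A", "B", "B"],
            "x": [0.0, 100.0, 10.0, 200.0],
            "y": [0.0, 0.0, 0.0, 0.0],
            "cell_id": ["c1", "c2", "c2", "c3"],
        }
    )


@pytest.fixture
def toy_panel():
    return GenePanel(["A", "B"])
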
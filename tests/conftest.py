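import numpy as np
import pandas as pd
import pytest

import orthopan as op


@pytest.fixture
def panel() -> op.HaplomePanel:
    return op.default_panel()


def make_matrix(panel, rows, with_genes=True):
    """Build an OrthogroupMatrix from {og: {haplome: count}} dicts."""
    haps = list(panel.haplome_ids)
    counts = pd.DataFrame(
        [[rows[og].get(h, 0) for h in haps] for og in rows], index=list(rows), columns=haps
    )
    genes = None
    if with_genes:
        genes = pd.DataFrame(
            [
                [tuple(f"{og}.{h}.g{i}" for i in range(rows[og].get(h, 0))) for h in haps]
                for og in rows
            ],
            index=list(rows),
            columns=haps,
        )
    return op.OrthogroupMatrix(counts, genes)


@pytest.fixture
def toy_matrix(panel):
    """Five orthogroups, one per category: sizes 8, 7, 4, 2-same-acc, 1."""
    haps = list(panel.haplome_ids)
    rows = {
        "OG_core": {h: 1 for h in haps},
        "OG_soft": {h: 2 for h in haps[:7]},
        "OG_acc": {h: 1 for h in haps[:4]},
        "OG_accspec": {haps[0]: 1, haps[1]: 3},  # both haplomes of accession 1
        "OG_hapspec": {haps[5]: 1},
    }
    return make_matrix(panel, rows)


def random_panel(rng: np.random.Generator) -> op.HaplomePanel:
    """A random panel: 2-10 haplomes grouped into random accessions."""
    n = int(rng.integers(2, 11))
    n_acc = int(rng.integers(1, n + 1))
    haps = tuple(f"h{i}" for i in range(n))
    acc = {h: f"a{int(rng.integers(n_acc))}" for h in haps}
    return op.HaplomePanel(haps, acc)


def brute_force_category(presence, panel) -> str:
    """Independent rule-table oracle for orthogroup classification."""
    n = len(panel.haplome_ids)
    s = len(presence)
    n_acc = len({panel.accession_of[h] for h in presence})
    if s == n:
        return "core"
    if s == n - 1 and n >= 4:
        return "soft_core"
    if 3 <= s <= n - 2:
        return "accessory"
    if s == 2:
        return "accessory" if n_acc == 2 else "accession_specific"
    return "haplome_specific"


def naive_pan_core(matrix: op.OrthogroupMatrix, members) -> tuple[int, int]:
    """Per-orthogroup loop oracle for subset pan/core sizes."""
    pan = core = 0
    for og in matrix.orthogroup_ids:
        supported = {h for h in members if matrix.counts.loc[og, h] > 0}
        if supported:
            pan += 1
        if len(supported) == len(set(members)):
            core += 1
    return pan, core
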
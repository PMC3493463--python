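"""Module label matching and overlap accounting between two networks.

Two module assignments over the same gene universe are cross-tabulated;
each cell gets a one-sided Fisher exact (hypergeometric) p-value for
over-representation. Test-network modules are then greedily relabeled
to the color of their most significantly overlapping reference module,
so that matching colors across networks mean matching gene content.
Background accounting quantifies, per reference module, how many of its
genes dissolve into grey background in the test network.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .colors import GREY, color_sequence


def _check_universe(assign_a: pd.Series, assign_b: pd.Series) -> None:
    if not assign_a.index.equals(assign_b.index):
        only_a = assign_a.index.difference(assign_b.index)
        only_b = assign_b.index.difference(assign_a.index)
        if len(only_a) or len(only_b):
            raise ValueError(
                f"gene universes differ: {len(only_a)} only in first "
                f"({only_a[:5].tolist()}), {len(only_b)} only in second "
                f"({only_b[:5].tolist()})"
            )


def _label_order(assign: pd.Series) -> list[str]:
    sizes = assign.value_counts()
    labels = sorted((m for m in sizes.index if m != GREY),
                    key=lambda m: (-sizes[m], m))
    if GREY in sizes.index:
        labels.append(GREY)
    return labels


@dataclasses.dataclass
class OverlapTable:
    """Cross-tabulation of two module assignments with Fisher p-values."""

    counts: pd.DataFrame    # reference modules x test modules, gene counts
    p_values: pd.DataFrame  # one-sided enrichment p per cell

    @property
    def neg_log10_p(self) -> pd.DataFrame:
        return -np.log10(self.p_values.clip(lower=1e-300))


def overlap_table(assign_ref: pd.Series, assign_test: pd.Series) -> OverlapTable:
    """Overlap counts and one-sided Fisher exact p-values per label pair.

    Rows are reference labels, columns test labels (grey included on
    both sides, listed last); row sums equal reference module sizes and
    column sums equal test module sizes.
    """
    _check_universe(assign_ref, assign_test)
    assign_test = assign_test.loc[assign_ref.index]
    rows = _label_order(assign_ref)
    cols = _label_order(assign_test)
    counts = pd.crosstab(assign_ref, assign_test).reindex(
        index=rows, columns=cols, fill_value=0)
    N = len(assign_ref)
    row_sizes = counts.sum(axis=1)
    col_sizes = counts.sum(axis=0)
    p = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for r in rows:
        for c in cols:
            k = counts.loc[r, c]
            p.loc[r, c] = float(hypergeom.sf(k - 1, N, row_sizes[r],
                                             col_sizes[c]))
    counts.index.name = p.index.name = "reference"
    counts.columns.name = p.columns.name = "test"
    return OverlapTable(counts=counts, p_values=p)


def match_labels(
    assign_ref: pd.Series,
    assign_test: pd.Series,
    p_threshold: float = 0.05,
) -> pd.Series:
    """Relabel test modules to the colors of overlapping reference modules.

    Greedy one-to-one matching in order of increasing overlap p-value
    (ties broken by larger overlap count, then lexicographic labels):
    a test module takes the label of its most significantly overlapping
    unused reference module if p < ``p_threshold``. Unmatched test
    modules get fresh labels from the standard color sequence (largest
    first); grey always maps to grey. Idempotent.
    """
    table = overlap_table(assign_ref, assign_test)
    ref_labels = [m for m in table.counts.index if m != GREY]
    test_labels = [m for m in table.counts.columns if m != GREY]

    pairs = sorted(
        ((table.p_values.loc[r, t], -int(table.counts.loc[r, t]), r, t)
         for r in ref_labels for t in test_labels),
        key=lambda x: (x[0], x[1], x[2], x[3]),
    )
    mapping: dict[str, str] = {GREY: GREY}
    used_ref: set[str] = set()
    for p, negc, r, t in pairs:
        if p >= p_threshold or -negc == 0:
            break
        if t in mapping or r in used_ref:
            continue
        mapping[t] = r
        used_ref.add(r)

    unmatched = [t for t in test_labels if t not in mapping]
    taken = set(ref_labels) | set(mapping.values())
    fresh = color_sequence(skip=taken)
    sizes = assign_test.value_counts()
    for t in sorted(unmatched, key=lambda m: (-sizes[m], m)):
        mapping[t] = next(fresh)
    return assign_test.map(mapping).rename(assign_test.name)


def background_accounting(
    assign_ref: pd.Series, assign_test: pd.Series
) -> pd.DataFrame:
    """Per-reference-module accounting of test-network background genes.

    Columns: ``size``; ``frac_grey_in_test`` — fraction of the module's
    genes that are grey in the test network; ``share_of_test_grey`` —
    the module's share of the whole test-grey pool (NaN when the test
    network has no grey genes); ``top_single_module_prop`` — the
    module's highest proportion of genes landing in any single non-grey
    test module.
    """
    _check_universe(assign_ref, assign_test)
    assign_test = assign_test.loc[assign_ref.index]
    total_grey = int((assign_test == GREY).sum())
    rows = []
    sizes = assign_ref.value_counts()
    for module in sorted((m for m in sizes.index if m != GREY),
                         key=lambda m: (-sizes[m], m)):
        members = assign_ref.index[assign_ref == module]
        in_test = assign_test.loc[members]
        n_grey = int((in_test == GREY).sum())
        non_grey = in_test[in_test != GREY]
        top = (non_grey.value_counts().max() / len(members)
               if len(non_grey) else 0.0)
        rows.append({
            "module": module,
            "size": len(members),
            "frac_grey_in_test": n_grey / len(members),
            "share_of_test_grey": (n_grey / total_grey if total_grey
                                   else np.nan),
            "top_single_module_prop": float(top),
        })
    return pd.DataFrame(rows).set_index("module")
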
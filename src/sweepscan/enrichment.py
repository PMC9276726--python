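"""Gene-set over-representation testing (GO/KEGG-style) with the
upper-tail hypergeometric test.

Given a candidate gene list, a universe, and a GMT collection, each set is
tested with P(X >= k) where X ~ Hypergeometric(N, K, n): N universe genes,
K of them in the set, n selected, k overlap. Raw p < 0.05 is the default
significance flag (Benjamini-Hochberg q-values are reported alongside).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class GeneSetCollection:
    """Named gene sets, as read from a GMT file (set id, description, members)."""

    def __init__(self, sets: Mapping[str, set], descriptions: Mapping[str, str] | None = None):
        self.sets = {k: set(v) for k, v in sets.items()}
        self.descriptions = dict(descriptions or {})

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT row: {line[:80]!r}")
                sets[fields[0]] = set(fields[2:])
                desc[fields[0]] = fields[1]
        return cls(sets, desc)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                d = self.descriptions.get(name, "")
                fh.write("\t".join([name, d] + sorted(members)) + "\n")

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_enrich(
    selected: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` in each set.

    Sets (and the selected list) are intersected with the universe before
    testing. Returns a DataFrame sorted by p with columns set_id, k, K, n,
    N, p_value, q_value (BH), significant (p < alpha).
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selected gene list")
    if not selected <= universe:
        raise ValueError(
            f"{len(selected - universe)} selected genes are not in the universe"
        )
    N, n = len(universe), len(selected)
    rows = []
    for set_id, members in collection.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        # P(X >= k); sf(k-1) == 1 for k == 0
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_value"] < alpha
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return df
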
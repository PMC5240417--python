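"""Three-species ortholog groups and group-level count integration.

Groups are the connected components of the pairwise ortholog graph, with a
universal identifier per group.  Each group holds at most one gene per
species; components with several genes of the same species (many-to-many
orthology) keep only the lexicographically first gene of that species and
demote the rest to singleton groups, because the expression analysis needs
exactly one count row per species per group.  Singleton genes (no ortholog
anywhere) become one-member groups whose counts in the other species are
structural zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import InputError

PAIR_COLUMNS = ("species_a", "gene_a", "species_b", "gene_b")


@dataclass(frozen=True)
class OrthologPair:
    species_a: str
    gene_a: str
    species_b: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise InputError(f"self-species pair: {self.species_a} {self.gene_a}/{self.gene_b}")


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller tuple becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def pairs_from_frame(table: pd.DataFrame) -> list[OrthologPair]:
    missing = [c for c in PAIR_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"ortholog pair table lacks columns: {missing}")
    return [
        OrthologPair(str(r.species_a), str(r.gene_a), str(r.species_b), str(r.gene_b))
        for r in table.itertuples(index=False)
    ]


def build_groups(
    pairs: list[OrthologPair],
    unigene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Connected components of the ortholog graph as a group table.

    Parameters
    ----------
    pairs
        pairwise ortholog links; every referenced gene must appear in the
        unigene set of its species.
    unigene_sets
        ``{species: set of unigene ids}``; genes with no pair become
        singleton groups.

    Returns
    -------
    DataFrame with ``group_id`` plus one column per species holding the
    member gene id or NA.  Group ids are assigned deterministically from
    the sorted member lists.
    """
    species = sorted(unigene_sets)
    for p in pairs:
        for sp, gene in ((p.species_a, p.gene_a), (p.species_b, p.gene_b)):
            if sp not in unigene_sets:
                raise InputError(f"pair references unknown species: {sp}")
            if gene not in unigene_sets[sp]:
                raise InputError(f"pair references unknown unigene: {sp}:{gene}")
    uf = _UnionFind()
    for sp in species:
        for gene in unigene_sets[sp]:
            uf.find((sp, gene))
    for p in pairs:
        uf.union((p.species_a, p.gene_a), (p.species_b, p.gene_b))

    components: dict[tuple, list[tuple]] = {}
    for node in uf.parent:
        components.setdefault(uf.find(node), []).append(node)

    member_rows: list[dict[str, str]] = []
    for nodes in components.values():
        row: dict[str, str] = {}
        leftovers: list[tuple] = []
        for sp, gene in sorted(nodes):
            if sp in row:  # many-to-many: keep lexicographically first
                leftovers.append((sp, gene))
            else:
                row[sp] = gene
        member_rows.append(row)
        member_rows.extend({sp: gene} for sp, gene in leftovers)

    member_rows.sort(key=lambda row: sorted(row.items()))
    table = pd.DataFrame(
        [
            {"group_id": f"OG{i:06d}", **{sp: row.get(sp, pd.NA) for sp in species}}
            for i, row in enumerate(member_rows)
        ],
        columns=["group_id", *species],
    )
    return table


def counts_to_groups(
    groups: pd.DataFrame,
    matrices: dict[str, CountMatrix],
) -> CountMatrix:
    """Assemble the group-level count matrix across the three species.

    Each group's row concatenates its member's counts from every species'
    samples; species without a member contribute zeros (the singleton
    zero-fill convention).
    """
    species = [c for c in groups.columns if c != "group_id"]
    blocks = []
    metas = []
    for sp in species:
        if sp not in matrices:
            raise InputError(f"no count matrix for species {sp}")
        cm = matrices[sp]
        members = groups[sp]
        known = members.dropna()
        missing = set(known) - set(cm.counts.index)
        if missing:
            raise InputError(f"{sp}: group members without counts: {sorted(missing)[:5]}")
        block = pd.DataFrame(
            0, index=groups["group_id"], columns=cm.counts.columns, dtype=np.int64
        )
        mask = members.notna().to_numpy()
        block.iloc[mask] = cm.counts.loc[members[mask]].to_numpy()
        blocks.append(block)
        metas.append(cm.samples)
    counts = pd.concat(blocks, axis=1)
    samples = pd.concat(metas, ignore_index=True)
    return CountMatrix(counts, samples)


def venn_counts(groups: pd.DataFrame) -> dict:
    """Counts of the seven Venn regions of the three unigene sets.

    Keys: ``only_<species>``, ``<a>&<b>`` for each species pair (present in
    exactly those two), ``all``, and ``union`` (= number of groups).
    """
    species = [c for c in groups.columns if c != "group_id"]
    present = groups[species].notna()
    out: dict[str, int] = {}
    for sp in species:
        only = present[sp] & ~present[[s for s in species if s != sp]].any(axis=1)
        out[f"only_{sp}"] = int(only.sum())
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            rest = [s for s in species if s not in (a, b)]
            mask = present[a] & present[b]
            if rest:
                mask &= ~present[rest].any(axis=1)
            out[f"{a}&{b}"] = int(mask.sum())
    out["all"] = int(present.all(axis=1).sum())
    out["union"] = int(len(groups))
    return out
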
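"""Tree and trait-table input/output.

Trees are held as rooted :class:`dendropy.Tree` objects with strictly
bifurcating topology (polytomies are resolved deterministically with
zero-length branches at read time) and non-negative branch lengths.
Discrete characters are bound to trees through :class:`CharacterMatrix`,
which enforces an exact tip/state cover before any comparative analysis
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import BindingError, TreeError, UnknownTipError

__all__ = [
    "CharacterMatrix",
    "HostPlantTable",
    "read_tree",
    "write_tree",
    "tip_labels",
    "tree_height",
    "prune_to_representatives",
    "bind_traits",
    "read_trait_table",
]


@dataclass
class CharacterMatrix:
    """Tip label -> discrete state assignment for one character.

    Parameters
    ----------
    states
        Mapping from tip label to state index in ``[0, k)``.
    state_names
        Ordered state labels; index ``i`` names state ``i``.
    """

    states: dict[str, int]
    state_names: Sequence[str]

    def __post_init__(self):
        k = len(self.state_names)
        for tip, s in self.states.items():
            if not (0 <= int(s) < k):
                raise ValueError(f"state index {s} for tip {tip!r} outside [0, {k})")
        self.states = {str(t): int(s) for t, s in self.states.items()}
        self.state_names = list(self.state_names)

    @property
    def k(self) -> int:
        return len(self.state_names)

    @classmethod
    def from_labels(cls, labels: Mapping[str, str], state_names: Sequence[str]) -> "CharacterMatrix":
        index = {name: i for i, name in enumerate(state_names)}
        try:
            states = {tip: index[val] for tip, val in labels.items()}
        except KeyError as exc:
            raise ValueError(f"unknown state label {exc.args[0]!r}") from exc
        return cls(states, state_names)

    def name_of(self, tip: str) -> str:
        return self.state_names[self.states[tip]]


@dataclass
class HostPlantTable:
    """Per-species host-plant ecology: family, toxicity, vegetation density, range.

    ``toxicity`` values are ``toxic``/``nontoxic``; ``vegetation`` values are
    ``sparse``/``dense``; ``distribution`` values are ``temperate``/
    ``tropical``/``both``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("family", "toxicity", "vegetation", "distribution")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"host table missing columns {missing}")
        bad_tox = set(self.table["toxicity"]) - {"toxic", "nontoxic"}
        bad_veg = set(self.table["vegetation"]) - {"sparse", "dense"}
        bad_dist = set(self.table["distribution"]) - {"temperate", "tropical", "both"}
        problems = []
        if bad_tox:
            problems.append(f"toxicity values {sorted(bad_tox)}")
        if bad_veg:
            problems.append(f"vegetation values {sorted(bad_veg)}")
        if bad_dist:
            problems.append(f"distribution values {sorted(bad_dist)}")
        if problems:
            raise ValueError("invalid host table: " + "; ".join(problems))

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def binary(self, column: str, one_level: str) -> dict[str, int]:
        """0/1 encoding of a column, with `one_level` (and, for distribution,
        the mixed level 'both') coded 1."""
        levels = {one_level}
        if column == "distribution" and one_level == "tropical":
            levels.add("both")
        return {sp: int(v in levels) for sp, v in self.table[column].items()}


def read_tree(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, validating labels and branch lengths.

    Polytomies are resolved into bifurcations with zero-length internal
    branches, in dendropy's deterministic input order. Bracketed comments
    are skipped by the reader. Raises :class:`TreeError` on malformed
    input, duplicate tips, or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise TreeError(f"Newick parse failure: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def write_tree(tree: dendropy.Tree) -> str:
    """Serialize to Newick with branch lengths at full precision."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        unquoted_underscores=True,
    ).strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def prune_to_representatives(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on `keep`, suppressing unifurcations (lengths summed).

    Patristic distances among kept tips are conserved. Raises
    :class:`UnknownTipError` for labels absent from the tree.
    """
    keep = set(keep)
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise UnknownTipError(f"tips not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to keep")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    pruned.is_rooted = True
    for edge in pruned.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return pruned


def bind_traits(tree: dendropy.Tree, matrix: CharacterMatrix) -> tuple[dendropy.Tree, CharacterMatrix]:
    """Validate that tree tips and matrix rows cover each other exactly.

    Returns the pair unchanged on success; raises :class:`BindingError`
    naming every offending tip/species otherwise.
    """
    tips = set(tip_labels(tree))
    species = set(matrix.states)
    missing = tips - species
    extra = species - tips
    if missing or extra:
        raise BindingError(missing_states=missing, extra_species=extra)
    return tree, matrix


def read_trait_table(path_or_buf) -> pd.DataFrame:
    """Read a species-indexed trait CSV (column `species` becomes the index)."""
    df = pd.read_csv(path_or_buf)
    if "species" not in df.columns:
        raise ValueError("trait table needs a 'species' column")
    return df.set_index("species")
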
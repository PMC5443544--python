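"""Core containers: landmark configurations, datasets, and phylogenies.

A landmark configuration is one anchor's k x 2 coordinate matrix plus its
specimen/species/side labels; landmark index is the homology correspondence,
so index i refers to the same anatomical point in every configuration of a
dataset.  Phylogenies are rooted trees with optional branch lengths, stored
in flat preorder arrays so the comparative algorithms can traverse them
without a tree library in the loop.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import ParseError, ValidationError

ANCHOR_SIDES = ("ventral", "dorsal")

#: Branch lengths smaller than this are floored before any division.
LENGTH_FLOOR = 1e-8


@dataclass
class LandmarkConfiguration:
    """One digitized anchor: k landmarks in 2-D with identity labels.

    ``scale_factor`` is the physical length per digitizer unit (the TPS
    SCALE= convention); ``None`` means no scale was recorded.
    """

    specimen_id: str
    species_id: str
    anchor_side: str
    coords: np.ndarray
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"configuration {self.specimen_id!r}: coords must be k x 2, "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValidationError(
                f"configuration {self.specimen_id!r}: need at least 3 landmarks, "
                f"got {self.coords.shape[0]} (shape is undefined below 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"configuration {self.specimen_id!r}: non-finite coordinates"
            )
        if self.anchor_side not in ANCHOR_SIDES:
            raise ValidationError(
                f"configuration {self.specimen_id!r}: anchor_side must be one of "
                f"{ANCHOR_SIDES}, got {self.anchor_side!r}"
            )
        if self.scale_factor is not None and not self.scale_factor > 0:
            raise ValidationError(
                f"configuration {self.specimen_id!r}: scale_factor must be positive"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def scaled_coords(self, scale_policy: str = "ignore") -> np.ndarray:
        """Coordinates with the digitizer scale applied or not.

        ``apply`` multiplies by ``scale_factor`` when present; ``ignore``
        returns the coordinates as digitized.
        """
        if scale_policy not in ("apply", "ignore"):
            raise ValueError(f"unknown scale_policy {scale_policy!r}")
        if scale_policy == "apply" and self.scale_factor is not None:
            return self.coords * self.scale_factor
        return self.coords.copy()


@dataclass
class LandmarkDataset:
    """An ordered collection of configurations sharing the landmark scheme."""

    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValidationError("dataset has no configurations")
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValidationError(
                f"inconsistent landmark counts across configurations: {sorted(ks)}"
            )
        seen: set[tuple[str, str]] = set()
        for c in self.configurations:
            key = (c.specimen_id, c.anchor_side)
            if key in seen:
                raise ValidationError(
                    f"duplicate specimen_id/anchor_side pair {key!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def species_ids(self) -> list[str]:
        return [c.species_id for c in self.configurations]

    @property
    def sides(self) -> list[str]:
        return [c.anchor_side for c in self.configurations]

    def species(self) -> list[str]:
        """Distinct species in first-appearance order."""
        out: list[str] = []
        for c in self.configurations:
            if c.species_id not in out:
                out.append(c.species_id)
        return out

    def filter_side(self, side: str) -> "LandmarkDataset":
        if side not in ANCHOR_SIDES:
            raise ValueError(f"unknown anchor side {side!r}")
        subset = [c for c in self.configurations if c.anchor_side == side]
        if not subset:
            raise ValidationError(f"no configurations with anchor_side={side!r}")
        return LandmarkDataset(subset)

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset([self.configurations[i] for i in indices])

    def exclude_specimens(self, specimen_ids: Iterable[str]) -> "LandmarkDataset":
        drop = set(specimen_ids)
        keep = [c for c in self.configurations if c.specimen_id not in drop]
        if not keep:
            raise ValidationError("excluding these specimens empties the dataset")
        return LandmarkDataset(keep)

    def coords_array(self, scale_policy: str = "ignore") -> np.ndarray:
        """All configurations as one n x k x 2 array."""
        return np.stack([c.scaled_coords(scale_policy) for c in self.configurations])

    def validation_report(self, tree: "Phylogeny | None" = None) -> list[str]:
        """Human-readable warnings; empty list means no issues found."""
        report: list[str] = []
        if tree is not None:
            tips = set(tree.tip_labels)
            orphans = sorted({s for s in self.species_ids if s not in tips})
            if orphans:
                report.append(
                    "species without a matching tree tip: " + ", ".join(orphans)
                )
        return report


def _preorder(node: dendropy.Node) -> list[dendropy.Node]:
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(reversed(nd.child_nodes()))
    return out


@dataclass
class Phylogeny:
    """A rooted tree in flat preorder arrays.

    Node 0 is the root; ``parent[i]`` is the preorder index of node i's
    parent (-1 for the root); ``edge_length[i]`` is the length of the branch
    above node i, NaN when the input recorded none.  Tip labels are exact
    strings after whitespace trimming.
    """

    parent: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    labels: list[str | None]

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        root = tree.seed_node
        if len(root.child_nodes()) < 2:
            raise ParseError("tree root must have at least 2 children (rooted tree)")
        nodes = _preorder(root)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        edge_length = np.full(n, np.nan)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
            if nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise ParseError(f"negative branch length {nd.edge.length}")
                edge_length[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label.strip()
            elif nd.label is not None:
                labels[i] = str(nd.label).strip()
        obj = cls(parent=parent, children=children, edge_length=edge_length,
                  labels=labels)
        tips = obj.tip_labels
        if any(t is None for t in tips):
            raise ParseError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ParseError(f"duplicate tip labels: {dupes}")
        return obj

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ParseError(f"invalid Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    @classmethod
    def from_path(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def has_branch_lengths(self) -> bool:
        """True when every non-root branch has a recorded length."""
        mask = self.parent >= 0
        return bool(np.all(np.isfinite(self.edge_length[mask])))

    def lengths(self, default: float = 1.0, floor: float = LENGTH_FLOOR) -> np.ndarray:
        """Branch lengths with absent values replaced and a positivity floor.

        Absent lengths (a bare topology) default to ``default``; any length
        below ``floor`` is raised to it so downstream divisions are safe.
        """
        out = np.where(np.isfinite(self.edge_length), self.edge_length, default)
        out = np.maximum(out, floor)
        out[self.parent < 0] = 0.0  # root has no branch
        return out

    def tip_index_of(self, label: str) -> int:
        label = label.strip()
        for i in self.tip_indices:
            if self.labels[i] == label:
                return i
        raise KeyError(f"no tip labelled {label!r}")

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return order[::-1]

    # -- transformations ----------------------------------------------

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a bifurcating tree; new internal branches get zero length.

        Children beyond the first are peeled off left-to-right into a chain
        of zero-length nodes, which leaves all tip-to-tip path lengths
        unchanged.
        """
        if self.is_bifurcating():
            return self
        # rebuild through a nested-list representation
        parent = list(self.parent)
        children = [list(c) for c in self.children]
        edge = list(self.edge_length)
        labels = list(self.labels)
        i = 0
        while i < len(children):
            while len(children[i]) > 2:
                # new node adopts all children but the first
                new = len(children)
                adopted = children[i][1:]
                children[i] = [children[i][0], new]
                children.append(adopted)
                parent.append(i)
                edge.append(0.0)
                labels.append(None)
                for c in adopted:
                    parent[c] = new
            i += 1
        tree = Phylogeny(parent=np.array(parent), children=children,
                         edge_length=np.array(edge, dtype=float), labels=labels)
        return tree._reindex_preorder()

    def _reindex_preorder(self) -> "Phylogeny":
        order: list[int] = []
        stack = [int(np.where(self.parent < 0)[0][0])]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(reversed(self.children[nd]))
        pos = {old: new for new, old in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=int)
        edge = np.full(n, np.nan)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        for old in order:
            new = pos[old]
            if self.parent[old] >= 0:
                parent[new] = pos[self.parent[old]]
            edge[new] = self.edge_length[old]
            children[new] = [pos[c] for c in self.children[old]]
            labels[new] = self.labels[old]
        return Phylogeny(parent=parent, children=children, edge_length=edge,
                         labels=labels)

    def retain_tips(self, labels: Iterable[str]) -> "Phylogeny":
        """Induced subtree on the given tip labels.

        Unsampled tips are removed and resulting degree-2 internal nodes are
        suppressed, summing branch lengths through them (NaN-aware: a path
        with any recorded length keeps a length).
        """
        keep = {l.strip() for l in labels}
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise ValidationError(f"labels not in tree: {sorted(unknown)}")
        if keep == set(self.tip_labels):
            return self
        if len(keep) < 2:
            raise ValidationError("need at least 2 retained tips")

        # mark nodes with at least one retained tip below
        retained = [False] * self.n_nodes
        for nd in self.postorder():
            if not self.children[nd]:
                retained[nd] = self.labels[nd] in keep
            else:
                retained[nd] = any(retained[c] for c in self.children[nd])

        def nansum(a: float, b: float) -> float:
            if np.isnan(a) and np.isnan(b):
                return np.nan
            return (0.0 if np.isnan(a) else a) + (0.0 if np.isnan(b) else b)

        # rebuild recursively, suppressing single-child chains
        def build(nd: int, acc_len: float) -> tuple[list, float]:
            kids = [c for c in self.children[nd] if retained[c]]
            length = nansum(acc_len, self.edge_length[nd]) if self.parent[nd] >= 0 else np.nan
            if not kids:
                return ([self.labels[nd], [], length], length)
            if len(kids) == 1 and self.parent[nd] >= 0:
                return build(kids[0], length)
            sub = [build(c, np.nan)[0] for c in kids]
            if len(kids) == 1:  # root with a single retained child: descend
                return build(kids[0], np.nan)
            return ([self.labels[nd], sub, length], length)

        spec, _ = build(0, np.nan)

        parent: list[int] = []
        children: list[list[int]] = []
        edge: list[float] = []
        labels_out: list[str | None] = []

        def emit(node_spec, par: int) -> int:
            label, kids, length = node_spec
            idx = len(parent)
            parent.append(par)
            children.append([])
            edge.append(length)
            labels_out.append(label if not kids else None)
            if par >= 0:
                children[par].append(idx)
            for ks in kids:
                emit(ks, idx)
            return idx

        emit(spec, -1)
        return Phylogeny(
            parent=np.array(parent),
            children=children,
            edge_length=np.array(edge, dtype=float),
            labels=labels_out,
        )

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                s = f"({inner})"
                if self.labels[i]:
                    s += self.labels[i]
            else:
                s = self.labels[i] or ""
            if self.parent[i] >= 0 and np.isfinite(self.edge_length[i]):
                s += f":{self.edge_length[i]:.17g}"
            return s

        return fmt(0) + ";"
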
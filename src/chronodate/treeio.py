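"""Trees, alignments and MCMC traces: the core data model and its file formats.

Time is measured in units of 100 My throughout; tips are extant (age 0).
Calibrated trees are plain Newick with calibration densities attached to
internal nodes as quoted labels, e.g. ``((A,B)'B(0.25,0.337,0.01,0.1)',C);``,
mirroring how dating software prints fossil calibrations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .calibrations import CalibrationDensity, parse_calibration, format_calibration

__all__ = [
    "TimeTree",
    "CalibratedTree",
    "Alignment",
    "Trace",
    "TreeParseError",
    "CalibrationError",
    "AlignmentFormatError",
    "read_calibrated_newick",
    "write_calibrated_newick",
    "read_alignment",
    "read_trace",
    "write_trace",
]


class TreeParseError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class AlignmentFormatError(ValueError):
    pass


# nucleotide codes: A,C,G,T -> 0..3; anything ambiguous (-, ?, N, IUPAC) -> -1
_NUC_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class TimeTree:
    """Rooted binary tree with node ages.

    Nodes are indexed 0..2n-2: tips first (0..n-1, in ``tip_names`` order),
    then internal nodes.  ``parent[i]`` is -1 for the root.  Ages are in
    units of 100 My; tips sit at age 0.
    """

    tip_names: list[str]
    parent: np.ndarray  # (2n-1,) int
    ages: np.ndarray  # (2n-1,) float

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def internal_nodes(self) -> list[int]:
        return list(range(self.n_tips, self.n_nodes))

    def children(self, node: int) -> list[int]:
        return [int(c) for c in np.flatnonzero(self.parent == node)]

    def children_table(self) -> dict[int, list[int]]:
        table: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for child, par in enumerate(self.parent):
            if par >= 0:
                table[int(par)].append(child)
        return table

    def postorder(self) -> list[int]:
        """All nodes, children before parents."""
        order: list[int] = []
        stack = [self.root]
        table = self.children_table()
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(table[node])
        return order[::-1]

    def branches(self) -> list[tuple[int, int]]:
        """(child, parent) pairs for every non-root node; a branch is named
        by its child node."""
        return [(i, int(p)) for i, p in enumerate(self.parent) if p >= 0]

    def branch_durations(self) -> np.ndarray:
        """Elapsed time on each branch, ordered as :meth:`branches`."""
        return np.array([self.ages[p] - self.ages[c] for c, p in self.branches()])

    def mrca(self, names: list[str]) -> int:
        idx = [self.tip_names.index(n) for n in names]
        paths = []
        for i in idx:
            path = {i}
            while self.parent[i] >= 0:
                i = int(self.parent[i])
                path.add(i)
            paths.append(path)
        common = set.intersection(*paths)
        return min(common, key=lambda j: self.ages[j])

    def tip_descendants(self, node: int) -> frozenset[str]:
        table = self.children_table()
        out: list[str] = []
        stack = [node]
        while stack:
            k = stack.pop()
            if k < self.n_tips:
                out.append(self.tip_names[k])
            else:
                stack.extend(table[k])
        return frozenset(out)

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeParseError("a time tree needs at least 2 tips")
        if len(self.parent) != 2 * n - 1 or len(self.ages) != 2 * n - 1:
            raise TreeParseError("node arrays must have length 2n-1")
        if np.sum(self.parent < 0) != 1:
            raise TreeParseError("exactly one root expected")
        counts = np.bincount(self.parent[self.parent >= 0], minlength=self.n_nodes)
        if any(counts[:n] != 0):
            raise TreeParseError("tips cannot have children")
        if any(counts[n:] != 2):
            raise TreeParseError("tree must be binary")
        if np.any(self.ages < 0):
            raise TreeParseError("ages must be non-negative")
        for child, par in self.branches():
            if self.ages[par] <= self.ages[child]:
                raise TreeParseError(
                    f"node {par} (age {self.ages[par]}) not older than its "
                    f"child {child} (age {self.ages[child]})"
                )

    def copy(self) -> "TimeTree":
        return TimeTree(list(self.tip_names), self.parent.copy(), self.ages.copy())


@dataclass
class CalibratedTree:
    """A :class:`TimeTree` plus calibration densities on internal nodes."""

    tree: TimeTree
    calibrations: dict[int, CalibrationDensity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.calibrations:
            if node < self.tree.n_tips:
                raise CalibrationError(f"calibration attached to tip node {node}")

    def copy(self) -> "CalibratedTree":
        return CalibratedTree(self.tree.copy(), dict(self.calibrations))


def _tree_from_dendropy(dtree: dendropy.Tree) -> CalibratedTree:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    names = [lf.taxon.label if lf.taxon is not None else (lf.label or "") for lf in leaves]
    if len(set(names)) != len(names):
        raise TreeParseError("duplicate tip names")
    n = len(names)
    internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    if len(internals) != n - 1:
        raise TreeParseError("tree must be rooted and strictly binary")
    index: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    for j, nd in enumerate(internals):
        index[id(nd)] = n + j

    parent = np.full(2 * n - 1, -1, dtype=int)
    for nd in dtree.preorder_node_iter():
        for ch in nd.child_nodes():
            parent[index[id(ch)]] = index[id(nd)]

    # ages: use node depths from edge lengths when present, else rank-based
    has_lengths = any(nd.edge.length is not None for nd in dtree.preorder_node_iter() if nd.parent_node)
    ages = np.zeros(2 * n - 1)
    if has_lengths:
        depth = {id(dtree.seed_node): 0.0}
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None:
                ln = nd.edge.length if nd.edge.length is not None else 0.0
                depth[id(nd)] = depth[id(nd.parent_node)] + float(ln)
        maxd = max(depth.values())
        for nd in dtree.preorder_node_iter():
            ages[index[id(nd)]] = maxd - depth[id(nd)]
        ages[np.abs(ages) < 1e-12] = 0.0
    else:
        # no branch lengths: assign arbitrary valid ages by node height
        height = np.zeros(2 * n - 1, dtype=int)
        order = [nd for nd in dtree.postorder_node_iter()]
        for nd in order:
            if not nd.is_leaf():
                height[index[id(nd)]] = 1 + max(height[index[id(c)]] for c in nd.child_nodes())
        ages[:] = height.astype(float)

    cals: dict[int, CalibrationDensity] = {}
    for nd in dtree.preorder_node_iter():
        label = nd.label if not nd.is_leaf() else None
        tip_label = None
        if nd.is_leaf():
            # calibration text can only legally live on internal nodes
            tip_label = nd.taxon.label if nd.taxon is not None else nd.label
        if nd.is_leaf():
            continue
        if label:
            try:
                cals[index[id(nd)]] = parse_calibration(label)
            except CalibrationError as err:
                tips = sorted(
                    (c.taxon.label for c in nd.leaf_iter() if c.taxon is not None)
                )
                raise CalibrationError(f"node ({','.join(tips)}): {err}") from err
    tree = TimeTree(names, parent, ages)
    return CalibratedTree(tree, cals)


def read_calibrated_newick(text: str) -> CalibratedTree:
    """Parse an annotated Newick string into a :class:`CalibratedTree`.

    Calibrations are quoted internal-node labels of the form
    ``'B(0.25,0.337,0.01,0.1)'``; unannotated nodes carry no density.
    """
    if text.count("(") != text.count(")"):
        raise TreeParseError("unbalanced parentheses in Newick string")
    # a calibration string on a tip is a user error we must name explicitly
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as err:  # dendropy raises several error types
        raise TreeParseError(f"Newick parse failure: {err}") from err
    for lf in dtree.leaf_node_iter():
        name = lf.taxon.label if lf.taxon is not None else (lf.label or "")
        if "(" in name and ")" in name:
            raise CalibrationError(f"calibration annotation on a tip: {name!r}")
    return _tree_from_dendropy(dtree)


def write_calibrated_newick(ctree: CalibratedTree, digits: int = 8) -> str:
    """Serialize topology, ages (as branch lengths) and calibrations."""
    tree = ctree.tree

    def render(node: int) -> str:
        if node < tree.n_tips:
            core = tree.tip_names[node]
        else:
            kids = ",".join(render(c) for c in tree.children(node))
            label = ""
            if node in ctree.calibrations:
                label = f"'{format_calibration(ctree.calibrations[node])}'"
            core = f"({kids}){label}"
        par = tree.parent[node]
        if par >= 0:
            blen = tree.ages[par] - tree.ages[node]
            core += f":{blen:.{digits}g}"
        return core

    return render(tree.root) + ";"


# -- alignments -------------------------------------------------------------


@dataclass
class Alignment:
    """Sequence matrix (rows follow ``names``) with a per-site partition index.

    States are coded A,C,G,T -> 0..3 and every ambiguity (gap, ?, N, IUPAC
    codes) -> -1, i.e. fully ambiguous for the likelihood.
    """

    names: list[str]
    matrix: np.ndarray  # (n_seq, n_sites) int8
    partition_index: np.ndarray  # (n_sites,) int
    partition_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.partition_index = np.asarray(self.partition_index, dtype=int)
        if len(set(self.names)) != len(self.names):
            raise AlignmentFormatError("duplicate sequence names")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise AlignmentFormatError("matrix shape does not match names")
        if self.partition_index.shape != (self.matrix.shape[1],):
            raise AlignmentFormatError("partition index must cover all sites")
        used = set(self.partition_index.tolist())
        if not used.issubset(range(len(self.partition_names))):
            raise AlignmentFormatError("partition index out of range")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_partitions(self) -> int:
        return len(self.partition_names)

    def partition(self, p: int) -> np.ndarray:
        return self.matrix[:, self.partition_index == p]

    def species_present(self, p: int) -> list[str]:
        sub = self.partition(p)
        return [nm for nm, row in zip(self.names, sub) if np.any(row >= 0)]


def _encode_seq(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _NUC_CODE.get(ch, -1)
    return out


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise AlignmentFormatError("FASTA data before first header")
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def _parse_phylip(text: str) -> list[tuple[str, str]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AlignmentFormatError("empty PHYLIP file")
    head = lines[0].split()
    try:
        nseq, nsites = int(head[0]), int(head[1])
    except (IndexError, ValueError) as err:
        raise AlignmentFormatError("bad PHYLIP header") from err
    records: list[tuple[str, str]] = []
    for ln in lines[1 : 1 + nseq]:
        parts = ln.split()
        if len(parts) < 2:
            raise AlignmentFormatError(f"bad PHYLIP row: {ln!r}")
        records.append((parts[0], "".join(parts[1:])))
    if len(records) != nseq:
        raise AlignmentFormatError("PHYLIP row count does not match header")
    for _, seq in records:
        if len(seq) != nsites:
            raise AlignmentFormatError("PHYLIP sequence length does not match header")
    return records


def read_alignment(
    source,
    format: str = "fasta",
    partitions: list[tuple[int, int]] | None = None,
    partition_names: list[str] | None = None,
) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    ``partitions`` is a list of 1-based, inclusive ``(first, last)`` site
    ranges; they must be disjoint and jointly cover every column.  With no
    table, all sites form a single partition.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    if format == "fasta":
        records = _parse_fasta(text)
    elif format == "phylip":
        records = _parse_phylip(text)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not records:
        raise AlignmentFormatError("no sequences found")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
    nsites = lengths.pop()
    names = [nm for nm, _ in records]
    if len(set(names)) != len(names):
        raise AlignmentFormatError("duplicate tip names in alignment")
    matrix = np.vstack([_encode_seq(seq) for _, seq in records])

    if partitions is None:
        idx = np.zeros(nsites, dtype=int)
        pnames = partition_names or ["part1"]
    else:
        idx = np.full(nsites, -1, dtype=int)
        for p, (first, last) in enumerate(partitions):
            if not (1 <= first <= last <= nsites):
                raise AlignmentFormatError(f"partition range {(first, last)} out of bounds")
            if np.any(idx[first - 1 : last] >= 0):
                raise AlignmentFormatError("overlapping partition ranges")
            idx[first - 1 : last] = p
        if np.any(idx < 0):
            raise AlignmentFormatError("partition table does not cover all sites")
        pnames = partition_names or [f"part{p + 1}" for p in range(len(partitions))]
    return Alignment(names, matrix, idx, list(pnames))


# -- traces -----------------------------------------------------------------


class Trace:
    """Tab-separated MCMC trace: iteration index, node ages, locus rates,
    sigma2 and log-likelihood, one row per stored sample."""

    REQUIRED = ("iter", "lnL")

    def __init__(self, data: pd.DataFrame, meta: dict | None = None):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"trace missing required column {col!r}")
        self.data = data.reset_index(drop=True)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def age_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("t_")]

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy()


def write_trace(trace: Trace, path) -> None:
    header = ""
    if trace.meta:
        pairs = " ".join(f"{k}={v}" for k, v in sorted(trace.meta.items()))
        header = f"# {pairs}\n"
    body = trace.data.to_csv(sep="\t", index=False, float_format="%.17g")
    if hasattr(path, "write"):
        path.write(header + body)
    else:
        with open(path, "w") as fh:
            fh.write(header + body)


def read_trace(path) -> Trace:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        for pair in lines[start][1:].split():
            if "=" in pair:
                key, val = pair.split("=", 1)
                meta[key] = val
        start += 1
    frame = pd.read_csv(io.StringIO("\n".join(lines[start:])), sep="\t")
    for col in Trace.REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"trace file missing required column {col!r}")
    return Trace(frame, meta)
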
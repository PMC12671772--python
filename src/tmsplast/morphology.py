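"""Reduced CA1 pyramidal-cell morphology.

The cell is a labelled tree of cylindrical (optionally tapering) sections:
a somatic root, an apical trunk carrying three oblique side branches and a
two-branch distal tuft, two basal subtrees (two child branches each), and a
myelinated axon (initial segment, five nodes of Ranvier interleaved with six
myelinated internodes, and an unmyelinated terminal).  Layers are assigned by
label: basal dendrites lie in stratum oriens, trunk and obliques in stratum
radiatum, and the tuft in stratum lacunosum-moleculare.

Coordinates are soma-centred, in micrometres, with the apical trunk along +y
and the axon along -y; absolute coordinates matter because uniform-field
quasipotentials are evaluated at compartment centres.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RegionLabel",
    "Section",
    "Morphology",
    "CellLocation",
    "GeometryConfig",
    "MorphologyError",
    "SWCParseError",
    "build_reduced_ca1",
    "path_distance",
    "read_swc",
    "write_swc",
]


class RegionLabel(str, enum.Enum):
    SOMA = "soma"
    APICAL_TRUNK = "apical_trunk"
    OBLIQUE = "oblique"
    TUFT = "tuft"
    BASAL = "basal"
    AIS = "ais"
    NODE = "node"
    MYELIN = "myelin"
    AXON_TERMINAL = "axon_terminal"


#: dendritic labels (receive excitatory synapses; TTX-dendritic target)
DENDRITIC_LABELS = frozenset(
    {RegionLabel.APICAL_TRUNK, RegionLabel.OBLIQUE, RegionLabel.TUFT, RegionLabel.BASAL}
)
#: axonal labels (SWC type code 2)
AXONAL_LABELS = frozenset(
    {RegionLabel.AIS, RegionLabel.NODE, RegionLabel.MYELIN, RegionLabel.AXON_TERMINAL}
)
#: apical labels (SWC type code 4)
APICAL_LABELS = frozenset(
    {RegionLabel.APICAL_TRUNK, RegionLabel.OBLIQUE, RegionLabel.TUFT}
)

#: layer membership by label (layer assignment is by label, not by distance)
LAYER_OF_LABEL = {
    RegionLabel.BASAL: "stratum_oriens",
    RegionLabel.APICAL_TRUNK: "stratum_radiatum",
    RegionLabel.OBLIQUE: "stratum_radiatum",
    RegionLabel.TUFT: "stratum_lacunosum_moleculare",
}


class MorphologyError(ValueError):
    """Raised when a morphology violates a structural constraint."""


class SWCParseError(ValueError):
    """Raised on malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class Section:
    """A cylindrical (or linearly tapering) neurite segment.

    ``diam_start``/``diam_end`` give the end-to-end taper; ``points`` are
    ordered 3-D coordinates in µm whose cumulative chord length equals
    ``length`` within 1e-6 µm.  Children attach at the distal end of their
    parent section.
    """

    id: int
    parent_id: int | None
    label: RegionLabel
    length: float
    diam_start: float
    diam_end: float
    points: np.ndarray  # (k, 3) float64, µm
    n_segments: int = 1

    def __post_init__(self):
        if self.length <= 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if self.diam_start <= 0 or self.diam_end <= 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise MorphologyError(f"section {self.id}: need >= 2 points of dim 3")
        chord = float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))
        if abs(chord - self.length) > 1e-6:
            raise MorphologyError(
                f"section {self.id}: point chord length {chord:.8f} != length {self.length:.8f}"
            )

    def diameter_at(self, frac: float) -> float:
        return self.diam_start + (self.diam_end - self.diam_start) * frac

    def point_at(self, frac: float) -> np.ndarray:
        """Interpolate a 3-D coordinate at arc fraction ``frac``."""
        seg = np.diff(self.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = frac * cum[-1]
        i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1))
        local = 0.0 if seglen[i] == 0 else (s - cum[i]) / seglen[i]
        return self.points[i] + local * seg[i]

    def lateral_area(self, f0: float = 0.0, f1: float = 1.0) -> float:
        """Frustum lateral membrane area (µm²) of the arc interval [f0, f1]."""
        d0, d1 = self.diameter_at(f0), self.diameter_at(f1)
        return math.pi * 0.5 * (d0 + d1) * self.length * (f1 - f0)


@dataclass(frozen=True)
class CellLocation:
    """A point on the cell: a section id plus an arc fraction in [0, 1]."""

    section_id: int
    arc_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.arc_fraction <= 1.0:
            raise MorphologyError(
                f"arc_fraction {self.arc_fraction} outside [0, 1]"
            )


@dataclass
class Morphology:
    sections: dict[int, Section]
    layer_boundaries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._validate_tree()
        if not self.layer_boundaries:
            self.layer_boundaries = self._compute_layer_boundaries()

    # -- tree structure -------------------------------------------------
    def _validate_tree(self):
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly 1 root, found {len(roots)}")
        if roots[0].label is not RegionLabel.SOMA:
            raise MorphologyError("root section must be the soma")
        seen: set[int] = set()
        for s in self.sections.values():
            node, hops = s, 0
            while node.parent_id is not None:
                if node.parent_id not in self.sections:
                    raise MorphologyError(
                        f"section {node.id} references missing parent {node.parent_id}"
                    )
                node = self.sections[node.parent_id]
                hops += 1
                if hops > len(self.sections):
                    raise MorphologyError("cycle detected in parent references")
            seen.add(s.id)
        if seen != set(self.sections):
            raise MorphologyError("disconnected sections present")

    @property
    def root(self) -> Section:
        return next(s for s in self.sections.values() if s.parent_id is None)

    def children_of(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections.values() if s.parent_id == sec_id]

    def by_label(self, label: RegionLabel) -> list[Section]:
        return [s for s in self.sections.values() if s.label is label]

    def section_order(self) -> list[int]:
        """Section ids in breadth-first order from the root (parents first)."""
        order, queue = [], [self.root.id]
        while queue:
            sid = queue.pop(0)
            order.append(sid)
            queue.extend(sorted(c.id for c in self.children_of(sid)))
        return order

    # -- distances ------------------------------------------------------
    def section_start_distance(self, sec_id: int) -> float:
        """Somatic path distance (µm) of the proximal end of a section.

        The soma counts as a point at the origin: its own length does not
        contribute, so sections attached to the soma start at distance 0.
        """
        if sec_id not in self.sections:
            raise KeyError(f"unknown section id {sec_id}")
        d, node = 0.0, self.sections[sec_id]
        while node.parent_id is not None:
            parent = self.sections[node.parent_id]
            if parent.label is not RegionLabel.SOMA:
                d += parent.length
            node = parent
        return d

    def _compute_layer_boundaries(self) -> dict[str, tuple[float, float]]:
        bounds: dict[str, tuple[float, float]] = {}
        for sec in self.sections.values():
            layer = LAYER_OF_LABEL.get(sec.label)
            if layer is None:
                continue
            d0 = self.section_start_distance(sec.id)
            d1 = d0 + sec.length
            lo, hi = bounds.get(layer, (d0, d1))
            bounds[layer] = (min(lo, d0), max(hi, d1))
        return bounds

    def validate_reduced_ca1(self):
        """Assert the reduced-CA1 topology counts; raise naming the violation."""
        soma = self.root
        basal_primary = [
            c for c in self.children_of(soma.id) if c.label is RegionLabel.BASAL
        ]
        if len(basal_primary) != 2:
            raise MorphologyError(
                f"expected exactly 2 basal subtrees, found {len(basal_primary)}"
            )
        for b in basal_primary:
            kids = self.children_of(b.id)
            if len(kids) != 2 or any(k.label is not RegionLabel.BASAL for k in kids):
                raise MorphologyError(
                    f"basal subtree {b.id} must carry exactly 2 child branches"
                )
        obliques = self.by_label(RegionLabel.OBLIQUE)
        if len(obliques) != 3:
            raise MorphologyError(f"expected exactly 3 obliques, found {len(obliques)}")
        for o in obliques:
            if self.sections[o.parent_id].label is not RegionLabel.APICAL_TRUNK:
                raise MorphologyError(f"oblique {o.id} not attached to apical trunk")
        tuft = self.by_label(RegionLabel.TUFT)
        if len(tuft) != 2:
            raise MorphologyError(f"expected exactly 2 tuft branches, found {len(tuft)}")
        nodes = self.by_label(RegionLabel.NODE)
        myelin = self.by_label(RegionLabel.MYELIN)
        if len(nodes) != 5 or len(myelin) != 6:
            raise MorphologyError(
                f"axon must have 5 nodes and 6 myelin sections, "
                f"found {len(nodes)}/{len(myelin)}"
            )
        if len(self.by_label(RegionLabel.AIS)) != 1:
            raise MorphologyError("expected exactly 1 axon initial segment")
        if len(self.by_label(RegionLabel.AXON_TERMINAL)) != 1:
            raise MorphologyError("expected exactly 1 axon terminal")

    def summary(self) -> dict:
        """JSON-ready morphology summary."""
        per_label = {}
        for label in RegionLabel:
            secs = self.by_label(label)
            per_label[label.value] = {
                "n_sections": len(secs),
                "total_length_um": sum(s.length for s in secs),
                "total_area_um2": sum(s.lateral_area() for s in secs),
            }
        return {
            "n_sections": len(self.sections),
            "per_label": per_label,
            "layer_boundaries_um": {
                k: list(v) for k, v in self.layer_boundaries.items()
            },
        }


def path_distance(morph: Morphology, loc: CellLocation) -> float:
    """Arc-length distance (µm) from the soma centre to ``loc``.

    Locations on the soma itself resolve to 0.
    """
    if loc.section_id not in morph.sections:
        raise KeyError(f"unknown section id {loc.section_id}")
    sec = morph.sections[loc.section_id]
    if sec.label is RegionLabel.SOMA:
        return 0.0
    return morph.section_start_distance(sec.id) + loc.arc_fraction * sec.length


# ---------------------------------------------------------------------------
# Reduced CA1 builder
# ---------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    """Section dimensions of the reduced CA1 cell (µm).

    The trunk is built from ``len(trunk_section_lengths)`` chained sections so
    that obliques can attach at interior fractions of the full trunk; the
    taper ``trunk_diam_start -> trunk_diam_end`` spans the whole trunk.
    ``oblique_attach_fractions`` give the attachment points as fractions of
    the total trunk length and must coincide with section joints.
    """

    soma_length: float = 20.0
    soma_diam: float = 20.0
    trunk_section_lengths: tuple[float, ...] = (100.0, 100.0, 100.0, 100.0)
    trunk_diam_start: float = 4.0
    trunk_diam_end: float = 2.0
    oblique_attach_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    oblique_length: float = 150.0
    oblique_diam: float = 1.0
    tuft_length: float = 200.0
    tuft_diam: float = 0.8
    n_tuft: int = 2
    basal_primary_length: float = 150.0
    basal_child_length: float = 200.0
    basal_diam: float = 1.0
    n_basal: int = 2
    ais_length: float = 30.0
    ais_diam: float = 1.5
    node_length: float = 1.0
    node_diam: float = 1.5
    myelin_length: float = 60.0
    myelin_diam: float = 1.5
    terminal_length: float = 30.0
    terminal_diam: float = 1.0
    n_nodes: int = 5
    n_myelin: int = 6


def _straight_points(p0: np.ndarray, direction: np.ndarray, length: float) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.vstack([p0, p0 + d * length])


def build_reduced_ca1(config: GeometryConfig | None = None) -> Morphology:
    """Build the reduced CA1 pyramidal-cell morphology.

    Soma at the origin, apical trunk along +y, axon along -y.  The returned
    morphology satisfies the reduced-CA1 topology invariants (2 basal
    subtrees of 2 branches, 3 trunk-attached obliques, 2 tuft branches, an
    axon with 5 nodes interleaved with 6 myelinated internodes).
    """
    cfg = config or GeometryConfig()
    if len(cfg.oblique_attach_fractions) != 3:
        raise MorphologyError(
            f"reduced CA1 requires exactly 3 obliques, "
            f"got {len(cfg.oblique_attach_fractions)} attachment points"
        )
    if cfg.n_tuft != 2:
        raise MorphologyError(f"reduced CA1 requires exactly 2 tuft branches, got {cfg.n_tuft}")
    if cfg.n_basal != 2:
        raise MorphologyError(f"reduced CA1 requires exactly 2 basal subtrees, got {cfg.n_basal}")
    if cfg.n_nodes != 5 or cfg.n_myelin != 6:
        raise MorphologyError(
            f"reduced CA1 axon requires 5 nodes / 6 myelin sections, "
            f"got {cfg.n_nodes}/{cfg.n_myelin}"
        )

    trunk_total = sum(cfg.trunk_section_lengths)
    joints = np.concatenate([[0.0], np.cumsum(cfg.trunk_section_lengths)]) / trunk_total
    for f in cfg.oblique_attach_fractions:
        if not np.any(np.isclose(joints, f, atol=1e-9)):
            raise MorphologyError(
                f"oblique attachment fraction {f} does not coincide with a trunk joint"
            )

    sections: dict[int, Section] = {}
    next_id = 0

    def add(parent_id, label, length, d0, d1, p0, direction) -> Section:
        nonlocal next_id
        sec = Section(
            id=next_id,
            parent_id=parent_id,
            label=label,
            length=length,
            diam_start=d0,
            diam_end=d1,
            points=_straight_points(np.asarray(p0, float), direction, length),
        )
        sections[next_id] = sec
        next_id += 1
        return sec

    # soma: vertical cylinder centred at the origin
    soma = Section(
        id=next_id,
        parent_id=None,
        label=RegionLabel.SOMA,
        length=cfg.soma_length,
        diam_start=cfg.soma_diam,
        diam_end=cfg.soma_diam,
        points=np.array(
            [[0.0, -cfg.soma_length / 2, 0.0], [0.0, cfg.soma_length / 2, 0.0]]
        ),
    )
    sections[next_id] = soma
    next_id += 1

    # apical trunk: chained sections along +y starting at the soma top
    apex = np.array([0.0, cfg.soma_length / 2, 0.0])
    parent = soma.id
    trunk_ids = []
    pos = 0.0
    for L in cfg.trunk_section_lengths:
        f0, f1 = pos / trunk_total, (pos + L) / trunk_total
        d0 = cfg.trunk_diam_start + (cfg.trunk_diam_end - cfg.trunk_diam_start) * f0
        d1 = cfg.trunk_diam_start + (cfg.trunk_diam_end - cfg.trunk_diam_start) * f1
        sec = add(parent, RegionLabel.APICAL_TRUNK, L, d0, d1, apex, [0, 1, 0])
        trunk_ids.append(sec.id)
        apex = sec.points[-1]
        parent = sec.id
        pos += L

    # obliques attach at trunk joints, alternating +x / -x, tilted upward
    for k, f in enumerate(cfg.oblique_attach_fractions):
        j = int(np.argmin(np.abs(joints - f)))  # joint index; joint j ends section j-1
        host = trunk_ids[j - 1]
        origin = sections[host].points[-1]
        side = 1.0 if k % 2 == 0 else -1.0
        add(
            host,
            RegionLabel.OBLIQUE,
            cfg.oblique_length,
            cfg.oblique_diam,
            cfg.oblique_diam,
            origin,
            [side * 0.9, 0.45, 0.0],
        )

    # tuft branches fan out from the trunk end
    top = sections[trunk_ids[-1]].points[-1]
    for k in range(cfg.n_tuft):
        side = 1.0 if k % 2 == 0 else -1.0
        add(
            trunk_ids[-1],
            RegionLabel.TUFT,
            cfg.tuft_length,
            cfg.tuft_diam,
            cfg.tuft_diam,
            top,
            [side * 0.5, 1.0, 0.0],
        )

    # basal subtrees from the soma bottom
    base = np.array([0.0, -cfg.soma_length / 2, 0.0])
    for k in range(cfg.n_basal):
        side = 1.0 if k % 2 == 0 else -1.0
        prim = add(
            soma.id,
            RegionLabel.BASAL,
            cfg.basal_primary_length,
            cfg.basal_diam,
            cfg.basal_diam,
            base,
            [side * 0.8, -0.8, 0.0],
        )
        for m in range(2):
            spread = 1.0 if m == 0 else 0.35
            add(
                prim.id,
                RegionLabel.BASAL,
                cfg.basal_child_length,
                cfg.basal_diam,
                cfg.basal_diam,
                prim.points[-1],
                [side * spread, -1.0, 0.0],
            )

    # axon straight down -y: ais, then myelin/node alternation, then terminal
    p = base.copy()
    ais = add(soma.id, RegionLabel.AIS, cfg.ais_length, cfg.ais_diam, cfg.ais_diam, p, [0, -1, 0])
    parent, p = ais.id, ais.points[-1]
    for k in range(cfg.n_myelin):
        my = add(parent, RegionLabel.MYELIN, cfg.myelin_length, cfg.myelin_diam,
                 cfg.myelin_diam, p, [0, -1, 0])
        parent, p = my.id, my.points[-1]
        if k < cfg.n_nodes:
            nd = add(parent, RegionLabel.NODE, cfg.node_length, cfg.node_diam,
                     cfg.node_diam, p, [0, -1, 0])
            parent, p = nd.id, nd.points[-1]
    add(parent, RegionLabel.AXON_TERMINAL, cfg.terminal_length, cfg.terminal_diam,
        cfg.terminal_diam, p, [0, -1, 0])

    morph = Morphology(sections=sections)
    morph.validate_reduced_ca1()
    return morph


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_TYPE_OF_LABEL = {
    RegionLabel.SOMA: 1,
    RegionLabel.AIS: 2,
    RegionLabel.NODE: 2,
    RegionLabel.MYELIN: 2,
    RegionLabel.AXON_TERMINAL: 2,
    RegionLabel.BASAL: 3,
    RegionLabel.APICAL_TRUNK: 4,
    RegionLabel.OBLIQUE: 4,
    RegionLabel.TUFT: 4,
}

_GROUP_LABEL_OF_TYPE = {
    1: RegionLabel.SOMA,
    2: RegionLabel.AIS,
    3: RegionLabel.BASAL,
    4: RegionLabel.APICAL_TRUNK,
}


def write_swc(morph: Morphology, path) -> None:
    """Write standard 7-column SWC (1-based ids, radius in µm).

    Sub-labels within the axonal and apical groups are not expressible in
    SWC type codes (soma→1, axon→2, basal→3, apical→4), so each section's
    label is recorded in a ``# tmsplast-sec`` header comment keyed by the
    section's first node id.  :func:`read_swc` honours these; files without
    them are read with group-level labels and merged unbranched runs.
    """
    node_id = 0
    sec_last_node: dict[int, int] = {}
    rows = []
    hints = []
    for sid in morph.section_order():
        sec = morph.sections[sid]
        t = _SWC_TYPE_OF_LABEL[sec.label]
        parent_node = -1 if sec.parent_id is None else sec_last_node[sec.parent_id]
        hints.append((node_id + 1, sec.label.value))
        k = len(sec.points)
        for i in range(k):
            frac = i / (k - 1)
            node_id += 1
            x, y, z = sec.points[i]
            rows.append((node_id, t, x, y, z, sec.diameter_at(frac) / 2, parent_node))
            parent_node = node_id
        sec_last_node[sid] = parent_node

    lines = ["# Generated by tmsplast", "# id type x y z radius parent"]
    lines += [f"# tmsplast-sec {n} {lab}" for n, lab in hints]
    lines += [
        f"{r[0]} {r[1]} {r[2]:.9f} {r[3]:.9f} {r[4]:.9f} {r[5]:.9f} {r[6]}"
        for r in rows
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path) -> Morphology:
    """Read an SWC file into a :class:`Morphology`.

    Each maximal unbranched run of same-type nodes becomes one section
    (additionally split at ``# tmsplast-sec`` markers when present, which
    also recover sub-labels).  Type codes map to group labels
    (1 soma, 2 ais, 3 basal, 4 apical trunk).
    """
    sec_starts: dict[int, RegionLabel] = {}
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 3 and parts[0] == "tmsplast-sec":
                    sec_starts[int(parts[1])] = RegionLabel(parts[2])
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid, t = int(parts[0]), int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as e:
                raise SWCParseError(str(e), lineno) from None
            if t not in _GROUP_LABEL_OF_TYPE:
                raise SWCParseError(f"unknown SWC type code {t}", lineno)
            if nid in records:
                raise SWCParseError(f"duplicate node id {nid}", lineno)
            records[nid] = (t, x, y, z, r, parent)

    if not records:
        raise SWCParseError("empty SWC file")

    # validate parents / detect cycles
    for nid, rec in records.items():
        if rec[5] != -1 and rec[5] not in records:
            raise SWCParseError(f"node {nid} parented to missing id {rec[5]}")
    for nid in records:
        seen: set[int] = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise SWCParseError(f"cyclic parent references at node {nid}")
            seen.add(cur)
            cur = records[cur][5]

    children: dict[int, list[int]] = {nid: [] for nid in records}
    roots = []
    for nid, rec in records.items():
        if rec[5] == -1:
            roots.append(nid)
        else:
            children[rec[5]].append(nid)
    if len(roots) != 1:
        raise SWCParseError(f"expected exactly 1 root node, found {len(roots)}")

    sections: dict[int, Section] = {}
    sec_counter = 0

    def flush_section(node_ids: list[int], parent_sec: int | None) -> int:
        nonlocal sec_counter
        t = records[node_ids[-1]][0]
        pts = np.array([records[n][1:4] for n in node_ids], dtype=float)
        if len(pts) == 1:  # single-point (e.g. soma-only file): stub cylinder
            r = records[node_ids[0]][4]
            pts = np.vstack([pts[0] - [0.0, r, 0.0], pts[0] + [0.0, r, 0.0]])
            length, d0, d1 = 2 * r, 2 * r, 2 * r
        else:
            length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
            d0, d1 = 2 * records[node_ids[0]][4], 2 * records[node_ids[-1]][4]
        label = sec_starts.get(node_ids[0], _GROUP_LABEL_OF_TYPE[t])
        sec = Section(
            id=sec_counter, parent_id=parent_sec, label=label,
            length=length, diam_start=d0, diam_end=d1, points=pts,
        )
        sections[sec_counter] = sec
        sec_counter += 1
        return sec.id

    # walk the node tree splitting at branch points, type changes and markers
    root = roots[0]
    stack: list[tuple[int, list[int], int | None]] = [(root, [root], None)]
    while stack:
        nid, run, parent_sec = stack.pop()
        kids = children[nid]
        t = records[nid][0]
        split = (
            len(kids) != 1
            or records[kids[0]][0] != t
            or kids[0] in sec_starts
        )
        if split:
            sec_id = flush_section(run, parent_sec)
            for k in sorted(kids, reverse=True):
                stack.append((k, [k], sec_id))
        else:
            stack.append((kids[0], run + [kids[0]], parent_sec))

    return Morphology(sections=sections)
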
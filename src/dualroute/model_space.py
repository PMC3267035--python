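"""Hypothesis space for the auditory dual-route analysis.

A :class:`NetworkModel` is a small directed multigraph of neural sources with
typed extrinsic connections.  Two architectures form the core contrast:

``CS``
    dual-route model — auditory thalamus (MGB) projects to primary auditory
    cortex (A1) and *directly* to the amygdala (AMY), so salient input can
    reach AMY both through the cortical relay and through a subcortical
    shortcut.
``C``
    cortical-only model — identical, minus the two direct MGB→AMY
    connections.

Five validation variants replace the amygdala with other plausible bilateral
sources (hippocampus, a second A1-adjacent pair, inferior colliculus,
superior temporal gyrus, and STG without its A1 forward afferents) to test
whether sensor data can discriminate a deep amygdalar source from its
neighbours.

Models serialize to a one-file-per-model JSON document (see ``models/`` in
the repository root); :func:`parse_model` re-validates all structural
invariants on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from typing import Iterable

__all__ = [
    "SourceNode",
    "ConnectionSpec",
    "NetworkModel",
    "ModelError",
    "MODEL_IDS",
    "VALIDATION_VARIANTS",
    "REGION_INFO",
    "build_dual_route_model",
    "build_cortical_model",
    "build_validation_model",
    "build_model",
    "serialize_model",
    "parse_model",
]

#: region -> (depth_class, default eccentricity in the spherical geometry).
#: Eccentricity 1 is the scalp surface; deep structures sit near the centre.
REGION_INFO: dict[str, tuple[str, float]] = {
    "MGB": ("deep", 0.30),
    "A1": ("superficial", 0.85),
    "AMY": ("deep", 0.55),
    "HIPP": ("deep", 0.45),
    "A1X": ("superficial", 0.85),
    "IC": ("deep", 0.35),
    "STG": ("superficial", 0.90),
}

MODEL_IDS = ("CS", "C", "HIPP", "A1plus", "IC", "STG", "STG_nf")
VALIDATION_VARIANTS = ("HIPP", "A1plus", "IC", "STG", "STG_nf")

CTYPES = ("forward", "backward")
HEMISPHERES = ("L", "R")

#: default extrinsic conduction delay (milliseconds)
DEFAULT_EXTRINSIC_DELAY_MS = 16.0
#: conduction delay of the direct (monosynaptic, subcortical) thalamic
#: projections; the anatomical rationale of the direct route is speed
DEFAULT_SUBCORTICAL_DELAY_MS = 8.0
#: default prior on connection log-gains: N(0, 1/16)
DEFAULT_PRIOR_MEAN = 0.0
DEFAULT_PRIOR_VARIANCE = 1.0 / 16.0


class ModelError(ValueError):
    """A network document violates a structural invariant."""


@dataclass(frozen=True)
class SourceNode:
    label: str
    region: str
    hemisphere: str
    depth_class: str
    is_input: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGION_INFO:
            raise ModelError(
                f"node {self.label!r}: unknown region {self.region!r}; "
                f"allowed: {sorted(REGION_INFO)}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ModelError(
                f"node {self.label!r}: hemisphere must be one of {HEMISPHERES}"
            )
        expected_depth = REGION_INFO[self.region][0]
        if self.depth_class != expected_depth:
            raise ModelError(
                f"node {self.label!r}: region {self.region} is "
                f"{expected_depth}, got depth_class={self.depth_class!r}"
            )
        if self.is_input and self.region != "MGB":
            raise ModelError(
                f"node {self.label!r}: only MGB nodes receive exogenous input"
            )


@dataclass(frozen=True)
class ConnectionSpec:
    source_label: str
    target_label: str
    ctype: str
    prior_log_gain_mean: float = DEFAULT_PRIOR_MEAN
    prior_log_gain_variance: float = DEFAULT_PRIOR_VARIANCE
    delay_ms: float = DEFAULT_EXTRINSIC_DELAY_MS

    def __post_init__(self) -> None:
        if self.ctype not in CTYPES:
            raise ModelError(
                f"connection {self.source_label}->{self.target_label}: "
                f"ctype must be one of {CTYPES}, got {self.ctype!r}"
            )
        if self.source_label == self.target_label:
            raise ModelError(f"self-connection on {self.source_label!r}")
        if self.prior_log_gain_variance < 0:
            raise ModelError(
                f"connection {self.source_label}->{self.target_label}: "
                "negative prior variance"
            )
        if self.delay_ms < 0:
            raise ModelError(
                f"connection {self.source_label}->{self.target_label}: "
                "negative delay"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_label, self.target_label, self.ctype)


@dataclass(frozen=True)
class NetworkModel:
    """One architecture hypothesis: named sources plus typed connections."""

    model_id: str
    nodes: tuple[SourceNode, ...]
    connections: tuple[ConnectionSpec, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "connections", tuple(self.connections))
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.nodes)

    def node(self, label: str) -> SourceNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    @property
    def input_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.nodes if n.is_input)

    def connections_of_type(self, ctype: str) -> tuple[ConnectionSpec, ...]:
        return tuple(c for c in self.connections if c.ctype == ctype)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ModelError(
                f"unknown model_id {self.model_id!r}; allowed: {MODEL_IDS}"
            )
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ModelError(f"duplicate node labels: {dupes}")
        label_set = set(labels)
        keys = [c.key for c in self.connections]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ModelError(f"duplicate connections: {dupes}")
        for c in self.connections:
            for lab in (c.source_label, c.target_label):
                if lab not in label_set:
                    raise ModelError(
                        f"connection {c.source_label}->{c.target_label} "
                        f"references unknown node {lab!r}"
                    )
        if not self.input_labels:
            raise ModelError("model has no input (is_input) node")
        self._check_connected()
        self._check_reachable()

    def _adjacency(self, directed: bool) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n.label: set() for n in self.nodes}
        for c in self.connections:
            adj[c.source_label].add(c.target_label)
            if not directed:
                adj[c.target_label].add(c.source_label)
        return adj

    @staticmethod
    def _bfs(adj: dict[str, set[str]], seeds: Iterable[str]) -> set[str]:
        seen = set(seeds)
        stack = list(seen)
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def _check_connected(self) -> None:
        # hemispheres do not interact, so connectivity is required within
        # each weakly connected component: every component must contain an
        # input node (no free-floating sources)
        adj = self._adjacency(directed=False)
        inputs = set(self.input_labels)
        seen = self._bfs(adj, inputs)
        missing = set(adj) - seen
        if missing:
            raise ModelError(
                f"model {self.model_id}: nodes not connected to any input "
                f"component: {sorted(missing)}"
            )

    def _check_reachable(self) -> None:
        adj = self._adjacency(directed=True)
        seen = self._bfs(adj, self.input_labels)
        missing = set(adj) - seen
        if missing:
            raise ModelError(
                f"model {self.model_id}: nodes unreachable from input: "
                f"{sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _make_node(region: str, hemisphere: str) -> SourceNode:
    depth, _ = REGION_INFO[region]
    return SourceNode(
        label=f"{region}_{hemisphere}",
        region=region,
        hemisphere=hemisphere,
        depth_class=depth,
        is_input=(region == "MGB"),
    )


def _bilateral_connections(
    region_pairs: list[tuple[str, str, str]],
) -> list[ConnectionSpec]:
    """Expand per-hemisphere (source_region, target_region, ctype) triples."""
    out = []
    for hemi in HEMISPHERES:
        for src, tgt, ctype in region_pairs:
            out.append(
                ConnectionSpec(f"{src}_{hemi}", f"{tgt}_{hemi}", ctype)
            )
    return out


def build_dual_route_model(include_backward: bool = True) -> NetworkModel:
    """Dual-route model CS: cortical (MGB→A1→AMY) plus subcortical (MGB→AMY).

    Bilateral and non-interacting across hemispheres.  Reciprocal backward
    connections (A1→MGB, AMY→A1) are included by default so that the CS/C
    contrast isolates the direct subcortical link; set
    ``include_backward=False`` for a feed-forward-only variant.
    """
    return _build_substituted("CS", "AMY", include_backward=include_backward)


def build_cortical_model(include_backward: bool = True) -> NetworkModel:
    """Cortical-only model C: CS minus the two direct MGB→AMY connections."""
    cs = build_dual_route_model(include_backward=include_backward)
    keep = tuple(
        c
        for c in cs.connections
        if not (
            c.ctype == "forward"
            and c.source_label.startswith("MGB")
            and c.target_label.startswith("AMY")
        )
    )
    return NetworkModel(model_id="C", nodes=cs.nodes, connections=keep)


def _build_substituted(
    model_id: str, deep_region: str, include_backward: bool = True
) -> NetworkModel:
    """CS topology with the amygdala slot occupied by ``deep_region``."""
    nodes = [
        _make_node(region, hemi)
        for hemi in HEMISPHERES
        for region in ("MGB", "A1", deep_region)
    ]
    pairs = [
        ("MGB", "A1", "forward"),
        ("A1", deep_region, "forward"),
        ("MGB", deep_region, "forward"),
    ]
    if include_backward:
        pairs += [("A1", "MGB", "backward"), (deep_region, "A1", "backward")]
    connections = [
        replace(c, delay_ms=DEFAULT_SUBCORTICAL_DELAY_MS)
        if c.ctype == "forward"
        and c.source_label.startswith("MGB")
        and not c.target_label.startswith("A1_")
        else c
        for c in _bilateral_connections(pairs)
    ]
    return NetworkModel(
        model_id=model_id,
        nodes=tuple(nodes),
        connections=tuple(connections),
    )


def build_validation_model(variant: str) -> NetworkModel:
    """Build one of the five amygdala-substitution validation models.

    ``HIPP``/``IC``/``STG`` replace AMY by the bilateral hippocampus,
    inferior colliculus or superior temporal gyrus; ``A1plus`` adds a second
    bilateral A1-adjacent pair (A1X); ``STG_nf`` is STG with the A1→STG
    forward connections removed (backward retained).
    """
    if variant not in VALIDATION_VARIANTS:
        raise ModelError(
            f"unknown validation variant {variant!r}; "
            f"allowed: {VALIDATION_VARIANTS}"
        )
    if variant == "A1plus":
        return _build_substituted("A1plus", "A1X")
    if variant in ("HIPP", "IC"):
        return _build_substituted(variant, variant)
    stg = _build_substituted("STG", "STG")
    if variant == "STG":
        return stg
    keep = tuple(
        c
        for c in stg.connections
        if not (
            c.ctype == "forward"
            and c.source_label.startswith("A1")
            and c.target_label.startswith("STG")
        )
    )
    return NetworkModel(
        model_id="STG_nf",
        nodes=stg.nodes,
        connections=keep,
        notes=(
            "A1->STG forward connections removed; STG receives forward drive "
            "only via the direct MGB->STG link and cortical feedback via "
            "backward STG->A1 / A1->MGB paths"
        ),
    )


def build_model(model_id: str) -> NetworkModel:
    """Build any of the seven named models by id."""
    if model_id == "CS":
        return build_dual_route_model()
    if model_id == "C":
        return build_cortical_model()
    return build_validation_model(model_id)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_model(model: NetworkModel) -> str:
    doc = {
        "model_id": model.model_id,
        "notes": model.notes,
        "nodes": [asdict(n) for n in model.nodes],
        "connections": [asdict(c) for c in model.connections],
    }
    return json.dumps(doc, indent=2) + "\n"


def parse_model(text: str) -> NetworkModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed model document: {exc}") from exc
    for key in ("model_id", "nodes", "connections"):
        if key not in doc:
            raise ModelError(f"model document missing field {key!r}")
    try:
        nodes = tuple(SourceNode(**n) for n in doc["nodes"])
    except TypeError as exc:
        raise ModelError(f"bad node record: {exc}") from exc
    try:
        connections = tuple(ConnectionSpec(**c) for c in doc["connections"])
    except TypeError as exc:
        raise ModelError(f"bad connection record: {exc}") from exc
    return NetworkModel(
        model_id=doc["model_id"],
        nodes=nodes,
        connections=connections,
        notes=doc.get("notes", ""),
    )


def write_model_file(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_model(model))


def read_model_file(path) -> NetworkModel:
    with open(path) as fh:
        return parse_model(fh.read())
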
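"""Cognitive-network definitions over a bilateral brain parcellation.

A network is a named set of bilateral region names.  Every region expands to
a left and a right node, so a network with ``|regions|`` regions has
``n = 2 * |regions|`` nodes and ``n (n - 1) / 2`` within-network links
(unordered node pairs).  Region names resolve to integer parcellation labels
through an editable JSON dictionary; the package ships a synthetic default
covering the five networks it defines (default mode, attention, verbal
memory, memory, visuospatial working memory).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

HEMISPHERES = ("L", "R")


class NetworkError(ValueError):
    """Invalid network definition."""


class RegionLookupError(NetworkError):
    """Region names could not be resolved against the parcellation."""

    def __init__(self, network: str, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            f"network {network!r}: unresolved region name(s): {', '.join(missing)}"
        )


def node_name(region: str, hemi: str) -> str:
    if hemi not in HEMISPHERES:
        raise NetworkError(f"hemisphere must be one of {HEMISPHERES}, got {hemi!r}")
    return f"{region}_{hemi}"


@dataclass(frozen=True)
class NetworkDefinition:
    """A named cognitive network expanded to bilateral nodes.

    ``nodes`` lists node identities in canonical order (regions in listed
    order, left before right); ``label_map`` maps each node to its integer
    parcellation label.
    """

    name: str
    regions: tuple[str, ...]
    label_map: dict[str, int]

    def __post_init__(self):
        if not self.name:
            raise NetworkError("network name must be non-empty")
        if len(self.regions) == 0:
            raise NetworkError(f"network {self.name!r} has an empty region list")
        if len(set(self.regions)) != len(self.regions):
            raise NetworkError(f"network {self.name!r} lists a region twice")
        missing = [nd for nd in self.nodes if nd not in self.label_map]
        if missing:
            raise RegionLookupError(self.name, missing)
        labels = [self.label_map[nd] for nd in self.nodes]
        if len(set(labels)) != len(labels):
            raise NetworkError(f"network {self.name!r} has duplicate labels")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(
            node_name(region, h) for region in self.regions for h in HEMISPHERES
        )

    @property
    def n(self) -> int:
        """Node count (twice the bilateral region count)."""
        return 2 * len(self.regions)

    def labels(self) -> tuple[int, ...]:
        return tuple(self.label_map[nd] for nd in self.nodes)


@dataclass(frozen=True)
class LinkSet:
    """All within-network links: unordered node pairs in canonical order."""

    network_name: str
    node_order: tuple[str, ...]
    links: tuple[tuple[int, int], ...] = field(default=())

    @property
    def L(self) -> int:
        return len(self.links)

    def link_names(self) -> list[tuple[str, str]]:
        return [(self.node_order[i], self.node_order[j]) for i, j in self.links]


def canonical_link(i: int, j: int) -> tuple[int, int]:
    """Canonical identity of an unordered node-index pair."""
    if i == j:
        raise NetworkError("self-links are not defined")
    return (i, j) if i < j else (j, i)


def enumerate_links(net: NetworkDefinition) -> LinkSet:
    """All unordered node pairs of ``net``; ``L = n (n - 1) / 2``."""
    if net.n < 2:
        raise NetworkError(f"network {net.name!r} has fewer than 2 nodes")
    links = tuple(itertools.combinations(range(net.n), 2))
    return LinkSet(network_name=net.name, node_order=net.nodes, links=links)


# ---------------------------------------------------------------------------
# Parcellation and network-definition files


def _packaged(name: str) -> dict:
    with resources.files("cognet.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def load_parcellation(path: str | Path | None = None) -> dict[str, dict]:
    """Region dictionary: name -> {labels: {L, R}, tissue, weight}.

    With no path, the packaged synthetic default is returned.
    """
    doc = _packaged("parcellation.json") if path is None else json.loads(
        Path(path).read_text()
    )
    regions = doc["regions"] if "regions" in doc else doc
    out: dict[str, dict] = {}
    seen: set[int] = set()
    for name, spec in regions.items():
        labels = {h: int(spec["labels"][h]) for h in HEMISPHERES}
        for lab in labels.values():
            if lab <= 0:
                raise NetworkError(f"region {name!r}: labels must be positive")
            if lab in seen:
                raise NetworkError(f"region {name!r}: label {lab} reused")
            seen.add(lab)
        out[name] = {
            "labels": labels,
            "tissue": spec.get("tissue", "GM"),
            "weight": float(spec.get("weight", 1.0)),
        }
        if out[name]["tissue"] not in ("GM", "WM", "CSF"):
            raise NetworkError(
                f"region {name!r}: tissue must be GM, WM or CSF, "
                f"got {out[name]['tissue']!r}"
            )
    return out


def parcellation_label_map(parcellation: dict[str, dict]) -> dict[str, int]:
    """Node -> label over the whole parcellation."""
    return {
        node_name(region, h): spec["labels"][h]
        for region, spec in parcellation.items()
        for h in HEMISPHERES
    }


def load_networks(
    path: str | Path | None = None,
    parcellation: dict[str, dict] | None = None,
    skip_unresolvable: bool = False,
) -> list[NetworkDefinition]:
    """Load and validate network definitions against a parcellation.

    With no arguments this returns the five packaged networks resolved
    against the packaged parcellation.  ``skip_unresolvable`` drops networks
    whose regions are absent from the parcellation instead of raising (used
    when simulating against a reduced parcellation).
    """
    if parcellation is None:
        parcellation = load_parcellation()
    doc = _packaged("networks.json") if path is None else json.loads(
        Path(path).read_text()
    )
    node_labels = parcellation_label_map(parcellation)
    nets = []
    for entry in doc["networks"]:
        regions = tuple(entry["regions"])
        missing = [r for r in regions if r not in parcellation]
        if missing:
            if skip_unresolvable:
                continue
            raise RegionLookupError(entry.get("name", "?"), missing)
        label_map = {
            node_name(r, h): node_labels[node_name(r, h)]
            for r in regions
            for h in HEMISPHERES
        }
        # explicit per-network label overrides, if the document carries any
        for node, lab in entry.get("labels", {}).items():
            label_map[node] = int(lab)
        nets.append(
            NetworkDefinition(name=entry["name"], regions=regions, label_map=label_map)
        )
    if not nets and not skip_unresolvable:
        raise NetworkError("network-definition document lists no networks")
    return nets
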
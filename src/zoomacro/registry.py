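"""Plankton-net specifications and the nested zooplankton taxon registry.

Three nets sample overlapping mesozooplankton size ranges: the fine WP2
(200 um mesh), the Bongo (300 um) and the coarse Regent (680 um).  The taxon
registry is a forest rooted at ``Zooplankton`` whose 36 analysis groups mirror
the coarse ZooScan/Ecotaxa classification: broad metazoan/protist groups, the
Copepoda broken into its five main orders, and copepod families wherever the
imaging resolution allows, plus two "unidentified" buckets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class NetSpec:
    """A plankton net: mesh selectivity and tow geometry.

    ``retention_steepness`` is the logistic slope (per um) of the retention
    curve ``p(esd) = 1 / (1 + exp(-steepness * (esd - mesh_um)))``.  The
    default steepness of 5/mesh gives a retention probability >= 0.99 for
    organisms twice the mesh size.
    """

    net_id: str
    mesh_um: float
    opening_m2: float
    tow: str = "vertical_0_100m"
    retention_steepness: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.mesh_um <= 0:
            raise ValueError(f"mesh_um must be positive, got {self.mesh_um}")
        if self.retention_steepness == 0.0:
            object.__setattr__(self, "retention_steepness", 5.0 / self.mesh_um)


#: Default net registry.  Mesh sizes and mouth openings follow the standard
#: WP2 / Bongo / Regent rigs used for 200-680 um mesozooplankton sampling.
NET_REGISTRY: dict[str, NetSpec] = {
    "WP2": NetSpec("WP2", mesh_um=200.0, opening_m2=0.57, tow="vertical_0_100m"),
    "Bongo": NetSpec("Bongo", mesh_um=300.0, opening_m2=0.57, tow="oblique_0_500m"),
    "Regent": NetSpec("Regent", mesh_um=680.0, opening_m2=1.12, tow="oblique_0_500m"),
}

ROOT = "Zooplankton"

#: child -> parent links for the 36 analysis groups (forest rooted at ROOT).
_PARENTS: dict[str, str] = {
    # broad groups
    "Copepoda": ROOT,
    "Chaetognatha": ROOT,
    "Cnidaria": ROOT,
    "Tunicata": ROOT,
    "Eumalacostraca": ROOT,
    "Rhizaria": ROOT,
    "Pteropoda": ROOT,
    "Cladocera+Ostracoda": ROOT,
    # copepod orders
    "Calanoida": "Copepoda",
    "Cyclopoida": "Copepoda",
    "Poecilostomatoida": "Copepoda",
    "Harpacticoida": "Copepoda",
    "Monstrilloida": "Copepoda",
    # unidentified buckets
    "unidentified Copepoda": "Copepoda",
    "small unidentified Calanoida": "Calanoida",
    # calanoid families
    "Calanidae": "Calanoida",
    "Paracalanidae": "Calanoida",
    "Clausocalanidae": "Calanoida",
    "Eucalanidae": "Calanoida",
    "Euchaetidae": "Calanoida",
    "Temoridae": "Calanoida",
    "Candaciidae": "Calanoida",
    "Augaptilidae": "Calanoida",
    "Centropagidae": "Calanoida",
    "Metridinidae": "Calanoida",
    "Acartiidae": "Calanoida",
    "Heterorhabdidae": "Calanoida",
    "Lucicutiidae": "Calanoida",
    "Pontellidae": "Calanoida",
    # cyclopoid / poecilostomatoid / harpacticoid families
    "Oithonidae": "Cyclopoida",
    "Oncaeidae": "Poecilostomatoida",
    "Corycaeidae": "Poecilostomatoida",
    "Sapphirinidae": "Poecilostomatoida",
    "Harpacticidae": "Harpacticoida",
    "Ectinosomatidae": "Harpacticoida",
}

UNIDENTIFIED_BUCKETS = ("unidentified Copepoda", "small unidentified Calanoida")


class TaxonRegistry:
    """Nested taxon forest with rollup bookkeeping.

    Parameters
    ----------
    parents
        child -> parent mapping; every chain must reach ``root``.
    root
        Name of the total-community root group.
    """

    def __init__(self, parents: dict[str, str] | None = None, root: str = ROOT):
        self.root = root
        self.parents = dict(_PARENTS if parents is None else parents)
        self._validate()

    def _validate(self) -> None:
        for node in self.parents:
            seen = {node}
            cur = node
            while cur != self.root:
                cur = self.parents.get(cur)
                if cur is None:
                    raise ValueError(f"taxon {node!r} does not reach root {self.root!r}")
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy at {cur!r}")
                seen.add(cur)

    @property
    def nodes(self) -> list[str]:
        return [self.root] + sorted(self.parents)

    @property
    def leaves(self) -> list[str]:
        non_leaf = set(self.parents.values())
        return sorted(n for n in self.parents if n not in non_leaf)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == node)

    def ancestors(self, taxon: str, strict: bool = True) -> list[str]:
        """Return ``[taxon, parent, ..., root]``; the rollup chain.

        Unknown labels raise when ``strict`` else map to the root only.
        """
        if taxon == self.root:
            return [self.root]
        if taxon not in self.parents:
            if strict:
                raise KeyError(f"unresolvable taxon label: {taxon!r}")
            return [self.root]
        chain = [taxon]
        while chain[-1] != self.root:
            chain.append(self.parents[chain[-1]])
        return chain

    def order_of(self, taxon: str) -> str | None:
        """The copepod order a taxon belongs to, if any."""
        orders = set(self.children("Copepoda")) - set(UNIDENTIFIED_BUCKETS)
        for node in self.ancestors(taxon, strict=False):
            if node in orders:
                return node
        return None


def default_registry() -> TaxonRegistry:
    """The 36-group analysis registry."""
    return TaxonRegistry()


def flat_registry(groups: list[str], root: str = ROOT) -> TaxonRegistry:
    """A registry where every group hangs directly off the root.

    Used by the planted-cluster recovery experiments, which want a fixed
    number of leaf models (e.g. 24 groups in 4 response families).
    """
    return TaxonRegistry({g: root for g in groups}, root=root)
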
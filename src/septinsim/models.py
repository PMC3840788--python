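"""Subunit-order rules and geometric lattice construction for septin
filament cables.

Septin rods are palindromic oligomers of four subunit kinds
(Cdc3, Cdc10, Cdc11, Cdc12).  Polymerizing variants repeat the rod
end-to-end into filaments; Gic1 (optionally loaded with Cdc42-GppNHp)
cross-bridges adjacent filaments at the central Cdc10 pair, producing
the railroad-track cable geometry that this module encodes as explicit
3D lattices of subunit positions plus cross-bridge contact records.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "SubunitKind",
    "LigandKind",
    "ComplexVariant",
    "BindingSite",
    "LatticeSpec",
    "Subunit",
    "Bridge",
    "Lattice",
    "protomer_order",
    "ligand_binding_sites",
    "build_lattice",
    "expected_gap",
    "cdc10_per_bridge",
    "oligomer_state",
    "default_lattice_spec",
]


class SubunitKind(str, enum.Enum):
    """The four essential septin subunit kinds."""

    CDC3 = "Cdc3"
    CDC10 = "Cdc10"
    CDC11 = "Cdc11"
    CDC12 = "Cdc12"


class LigandKind(str, enum.Enum):
    """Non-septin ligands that decorate or bridge filaments."""

    GIC1 = "Gic1"
    CDC42_GDP = "Cdc42-GDP"
    CDC42_GTP = "Cdc42-GppNHp"


class ComplexVariant(str, enum.Enum):
    """Every complex variant with a distinct subunit order / binding rule."""

    WT = "WT"
    WT_GIC1 = "WT_GIC1"
    WT_GIC1_CDC42GTP = "WT_GIC1_CDC42GTP"
    WT_CDC42GDP = "WT_CDC42GDP"
    CDC11_DELTA = "CDC11_DELTA"
    CDC11_DELTA_GIC1 = "CDC11_DELTA_GIC1"
    CDC10_DELTA = "CDC10_DELTA"
    CDC10_TRUNC_GIC1 = "CDC10_TRUNC_GIC1"
    HIGH_SALT_OCTAMER = "HIGH_SALT_OCTAMER"
    CDC42GDP_OCTAMER = "CDC42GDP_OCTAMER"
    HEXAMER_NO_CDC10 = "HEXAMER_NO_CDC10"


_K = SubunitKind

# Wild-type octamer rod: Cdc11 caps, Cdc10 pair in the centre.
_WT_ORDER = (
    _K.CDC11, _K.CDC12, _K.CDC3, _K.CDC10,
    _K.CDC10, _K.CDC3, _K.CDC12, _K.CDC11,
)

_PROTOMER_ORDERS: dict[ComplexVariant, tuple[SubunitKind, ...]] = {
    ComplexVariant.WT: _WT_ORDER,
    ComplexVariant.WT_GIC1: _WT_ORDER,
    ComplexVariant.WT_GIC1_CDC42GTP: _WT_ORDER,
    ComplexVariant.WT_CDC42GDP: _WT_ORDER,
    ComplexVariant.HIGH_SALT_OCTAMER: _WT_ORDER,
    # Cdc11 removed, order otherwise preserved -> hexamer with Cdc10 caps.
    ComplexVariant.CDC11_DELTA: (
        _K.CDC10, _K.CDC3, _K.CDC12, _K.CDC12, _K.CDC3, _K.CDC10,
    ),
    ComplexVariant.CDC11_DELTA_GIC1: (
        _K.CDC10, _K.CDC3, _K.CDC12, _K.CDC12, _K.CDC3, _K.CDC10,
    ),
    # Cdc10 removed from the wild-type order.
    ComplexVariant.CDC10_DELTA: (
        _K.CDC11, _K.CDC12, _K.CDC3, _K.CDC3, _K.CDC12, _K.CDC11,
    ),
    # N-terminally truncated Cdc10 keeps the wild-type order.
    ComplexVariant.CDC10_TRUNC_GIC1: _WT_ORDER,
    # Cdc42-GDP-capped octamer: Cdc11 central, Cdc10 at both ends.
    ComplexVariant.CDC42GDP_OCTAMER: (
        _K.CDC10, _K.CDC3, _K.CDC12, _K.CDC11,
        _K.CDC11, _K.CDC12, _K.CDC3, _K.CDC10,
    ),
    # Cdc10-less hexamer released on filament dissociation; Cdc3 caps.
    ComplexVariant.HEXAMER_NO_CDC10: (
        _K.CDC3, _K.CDC12, _K.CDC11, _K.CDC11, _K.CDC12, _K.CDC3,
    ),
}

#: Variants that polymerize into filaments under the encoded rules.
POLYMERIZING_VARIANTS = frozenset(
    {
        ComplexVariant.WT,
        ComplexVariant.WT_GIC1,
        ComplexVariant.WT_GIC1_CDC42GTP,
        ComplexVariant.CDC11_DELTA_GIC1,
    }
)

#: Variants whose filaments carry periodic cross-bridges, with the bridging
#: ligand and the number of subunits each bridge occupies per filament.
_BRIDGE_RULES: dict[ComplexVariant, tuple[LigandKind, int, float]] = {
    # variant -> (ligand, bridge_span in subunits, mass scale)
    ComplexVariant.WT_GIC1: (LigandKind.GIC1, 2, 1.0),
    ComplexVariant.CDC11_DELTA_GIC1: (LigandKind.GIC1, 2, 1.0),
    # Gic1 loaded with Cdc42-GppNHp: bulkier bridge occupying four subunits.
    ComplexVariant.WT_GIC1_CDC42GTP: (LigandKind.CDC42_GTP, 4, 1.5),
}


@dataclass(frozen=True)
class BindingSite:
    """An adjacent Cdc10 pair eligible for ligand binding.

    ``cross_linking`` is False for bind-only sites (truncated Cdc10 still
    binds Gic1 but bridges are not formed).
    """

    indices: tuple[int, int]
    cross_linking: bool = True


@dataclass(frozen=True)
class LatticeSpec:
    """Geometric parameters of a filament-cable lattice.

    Lengths are in nanometres.  ``inter_filament_spacing`` is
    centre-to-centre.  ``bridge_period`` and ``bridge_span`` are counted
    in subunits along one filament.
    """

    n_filaments: int = 2
    n_repeats: int = 3
    subunit_diameter: float = 4.0
    inter_filament_spacing: float = 20.0
    bridge_period: int = 8
    bridge_span: int = 2
    randomize_starts: bool = False
    max_start_offset: int = 0
    bend_curvature: float = 0.0
    bridge_mass_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        if self.n_filaments and self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.subunit_diameter <= 0:
            raise ValueError("subunit_diameter must be positive")
        if self.n_filaments > 1 and (
            self.inter_filament_spacing <= self.subunit_diameter
        ):
            raise ValueError(
                "inter_filament_spacing must exceed subunit_diameter"
            )
        if self.bridge_period < self.bridge_span:
            raise ValueError("bridge_period must be >= bridge_span")
        if self.bridge_mass_scale <= 0:
            raise ValueError("bridge_mass_scale must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "LatticeSpec":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class Subunit:
    filament: int
    axial_index: int
    kind: SubunitKind
    position: tuple[float, float, float]  # (x, y, z) nm
    bridge_bound: bool = False


@dataclass(frozen=True)
class Bridge:
    """One cross-bridge: its axial centre and the subunits it occupies."""

    axial_position: float  # nm along the filament axis
    contacts: tuple[tuple[int, int], ...]  # (filament, axial_index) pairs
    ligand: LigandKind
    mass_scale: float = 1.0


@dataclass
class Lattice:
    """Ground-truth geometry: placed subunits plus cross-bridge records.

    The filament axis is x, filaments are laid out along y, and z is the
    beam direction of an untilted side-view acquisition.
    """

    spec: LatticeSpec
    variant: ComplexVariant
    subunits: list[Subunit] = field(default_factory=list)
    bridges: list[Bridge] = field(default_factory=list)
    seed: int = 0

    def subunit_lookup(self) -> dict[tuple[int, int], Subunit]:
        return {(s.filament, s.axial_index): s for s in self.subunits}

    def bridge_positions(self) -> np.ndarray:
        """Bridge centres as an (n, 3) array of (x, y, z) nm."""
        if not self.bridges:
            return np.empty((0, 3))
        lut = self.subunit_lookup()
        out = []
        for b in self.bridges:
            pts = np.array([lut[c].position for c in b.contacts])
            out.append(pts.mean(axis=0))
        return np.array(out)

    def to_table(self) -> str:
        """One subunit per row: filament, index, kind, x, y, z, bound."""
        buf = io.StringIO()
        buf.write("filament\taxial_index\tkind\tx_nm\ty_nm\tz_nm\tbridge_bound\n")
        for s in self.subunits:
            x, y, z = s.position
            buf.write(
                f"{s.filament}\t{s.axial_index}\t{s.kind.value}"
                f"\t{x:.6g}\t{y:.6g}\t{z:.6g}\t{int(s.bridge_bound)}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_table(cls, text: str, spec: LatticeSpec | None = None,
                   variant: ComplexVariant = ComplexVariant.WT) -> "Lattice":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        subunits = []
        for ln in lines[1:]:
            fil, idx, kind, x, y, z, bound = ln.split("\t")
            subunits.append(
                Subunit(
                    int(fil), int(idx), SubunitKind(kind),
                    (float(x), float(y), float(z)), bool(int(bound)),
                )
            )
        return cls(spec=spec or LatticeSpec(), variant=variant,
                   subunits=subunits)


def protomer_order(variant: ComplexVariant) -> list[SubunitKind]:
    """Return the ordered subunit block for a variant.

    For filament-forming variants this is the repeating protomer; for
    non-polymerizing variants it is the particle order.  Octamer and
    hexamer orders are palindromic (two-fold rotational symmetry).
    """
    try:
        variant = ComplexVariant(variant)
    except ValueError:
        raise ValueError(f"unknown complex variant: {variant!r}") from None
    return list(_PROTOMER_ORDERS[variant])


def ligand_binding_sites(
    order: list[SubunitKind],
    ligand: LigandKind,
    variant: ComplexVariant,
) -> list[BindingSite]:
    """Adjacent Cdc10-pair positions eligible for ligand binding.

    Both Gic1 and Cdc42-GDP target the Cdc10 pair.  For filament-forming
    variants the order is treated as one period, so the wrap-around pair
    (last, first) counts as adjacent.  An empty list is a valid result:
    variants lacking Cdc10 bind neither ligand, and N-terminally
    truncated Cdc10 does not bind Cdc42-GDP at all while binding Gic1
    without cross-linking (``cross_linking=False``).
    """
    if not order:
        raise ValueError("subunit order must be nonempty")
    variant = ComplexVariant(variant)
    ligand = LigandKind(ligand)

    truncated = variant is ComplexVariant.CDC10_TRUNC_GIC1
    if truncated and ligand is LigandKind.CDC42_GDP:
        return []
    if ligand is LigandKind.CDC42_GTP and variant not in (
        ComplexVariant.WT_GIC1_CDC42GTP,
    ):
        # Cdc42-GppNHp reaches septin only through Gic1.
        return []

    n = len(order)
    periodic = variant in POLYMERIZING_VARIANTS
    pairs = []
    limit = n if periodic else n - 1
    for i in range(limit):
        j = (i + 1) % n
        if order[i] is SubunitKind.CDC10 and order[j] is SubunitKind.CDC10:
            pairs.append((i, j))
    return [BindingSite(p, cross_linking=not truncated) for p in pairs]


def default_lattice_spec(variant: ComplexVariant, **overrides) -> LatticeSpec:
    """Lattice spec with the variant's bridge rule filled in.

    Bridge period is one per protomer (8 subunits for wild-type, 6 for
    the Cdc11-less hexamer); span and mass scale follow the variant's
    bridging ligand.
    """
    variant = ComplexVariant(variant)
    order = protomer_order(variant)
    kw = dict(bridge_period=len(order))
    if variant in _BRIDGE_RULES:
        _, span, mass = _BRIDGE_RULES[variant]
        kw.update(bridge_span=span, bridge_mass_scale=mass)
    kw.update(overrides)
    return LatticeSpec(**kw)


def build_lattice(
    spec: LatticeSpec, variant: ComplexVariant, seed: int = 0
) -> Lattice:
    """Lay filaments on parallel axes and place periodic cross-bridges.

    Filaments run along x and are spaced ``inter_filament_spacing``
    apart along y, centred on y = 0.  Bridges sit at the centre of each
    Cdc10 pair (in the unshifted register), every ``bridge_period``
    subunits, and record contacts with the ``bridge_span`` subunits they
    occupy on every filament within reach.  Deterministic in
    (spec, variant, seed).
    """
    variant = ComplexVariant(variant)
    if spec.n_filaments >= 1 and variant not in POLYMERIZING_VARIANTS:
        if variant in (ComplexVariant.WT_CDC42GDP,):
            raise ValueError(
                f"variant does not polymerize: {variant.value} "
                "(Cdc42-GDP dissociates filaments)"
            )
        raise ValueError(f"variant does not polymerize: {variant.value}")

    order = protomer_order(variant)
    n_per = len(order)
    d = spec.subunit_diameter
    rng = np.random.default_rng(seed)

    offsets = np.zeros(spec.n_filaments, dtype=int)
    if spec.randomize_starts and spec.max_start_offset > 0:
        offsets = rng.integers(0, spec.max_start_offset + 1,
                               size=spec.n_filaments)

    y0 = -(spec.n_filaments - 1) * spec.inter_filament_spacing / 2.0
    n_sub = n_per * spec.n_repeats

    subunits: list[Subunit] = []
    for f in range(spec.n_filaments):
        y = y0 + f * spec.inter_filament_spacing
        for a in range(n_sub):
            x = (a + offsets[f]) * d
            z = 0.0
            if spec.bend_curvature > 0:
                # circular-arc displacement of the filament axis in the
                # x-z plane; small-angle arc sagitta
                z = spec.bend_curvature * x * x / 2.0
            subunits.append(
                Subunit(f, a, order[a % n_per], (x, y, z))
            )

    bridges: list[Bridge] = []
    sites = []
    ligand = LigandKind.GIC1
    mass_scale = spec.bridge_mass_scale
    if variant in _BRIDGE_RULES:
        rule_ligand, _, _ = _BRIDGE_RULES[variant]
        ligand = rule_ligand
        sites = ligand_binding_sites(order, LigandKind.GIC1
                                     if rule_ligand is LigandKind.GIC1
                                     else LigandKind.CDC42_GTP, variant)
        # Cdc42-GppNHp bridges are still anchored at the Gic1 site
        if not sites:
            sites = ligand_binding_sites(order, LigandKind.GIC1, variant)
    sites = [s for s in sites if s.cross_linking]

    if sites and spec.n_filaments >= 1:
        site = sites[0]
        pair_centre_idx = (site.indices[0] + site.indices[1]) / 2.0
        if site.indices[1] < site.indices[0]:  # wrap-around pair
            pair_centre_idx = site.indices[0] + 0.5
        reach = spec.bridge_span / 2.0 - 0.5  # in subunit-index units
        for rep in range(spec.n_repeats):
            centre_idx = rep * n_per + pair_centre_idx
            contacts: list[tuple[int, int]] = []
            for f in range(spec.n_filaments):
                fil_contacts = [
                    (f, a)
                    for a in range(n_sub)
                    if abs(a + offsets[f] - centre_idx) <= reach + 1e-9
                ]
                # a filament participates only with a complete pair
                # (>= 2 contacted subunits); truncated pairs at
                # filament ends do not anchor a bridge
                if len(fil_contacts) >= 2:
                    contacts.extend(fil_contacts)
            if len(contacts) >= 2:
                bridges.append(
                    Bridge(centre_idx * d, tuple(contacts), ligand,
                           mass_scale)
                )

    bound = {c for b in bridges for c in b.contacts}
    subunits = [
        replace(s, bridge_bound=(s.filament, s.axial_index) in bound)
        for s in subunits
    ]
    return Lattice(spec=spec, variant=variant, subunits=subunits,
                   bridges=bridges, seed=seed)


def expected_gap(variant: ComplexVariant) -> int:
    """Free (un-bridged) subunits per filament between consecutive bridges.

    Computed analytically as protomer length minus bridge span.
    """
    variant = ComplexVariant(variant)
    if variant not in _BRIDGE_RULES:
        raise ValueError(
            f"variant has no cross-bridges: {variant.value}"
        )
    _, span, _ = _BRIDGE_RULES[variant]
    return len(protomer_order(variant)) - span


def cdc10_per_bridge(n_filaments: int) -> int:
    """Cdc10 subunits contacted by one cross-bridge: two per filament."""
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    return 2 * int(n_filaments)


def oligomer_state(observed_kda: float, monomer_kda: float) -> int:
    """Oligomeric state inferred from an observed vs monomer mass."""
    if observed_kda <= 0 or monomer_kda <= 0:
        raise ValueError("masses must be positive")
    return max(1, round(observed_kda / monomer_kda))
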
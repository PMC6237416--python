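"""Domain types for the reduced translocase-nucleosome model.

The system is described by 16 reduced coordinates: 14 histone-DNA contact
indexes ``x_j`` (one per half-integer superhelical location, SHL -6.5 ... +6.5,
in base pairs relative to the cycle-start registration) and two lobe contact
indexes ``y1``, ``y2`` tracking how far each RecA-like lobe of the translocase
has moved along the DNA.  A twist defect at integer SHL ``i`` is the derived
quantity ``d_i = x_{i+0.5} - x_{i-0.5}``: +1 for an extra base pair stored
between the flanking contacts, -1 for a missing one.

Energies are in units of kT (kT = 1), lengths in base pairs.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChemicalState",
    "ShlGrid",
    "SystemState",
    "DefectSiteParams",
    "ContactParams",
    "RemodelerParams",
    "SequenceProfile",
    "ParameterSet",
    "effective_params",
    "GRID",
]


class ChemicalState(enum.Enum):
    """Nucleotide occupancy of the translocase ATPase site."""

    APO = "apo"
    ATP = "atp"
    ADP = "adp"


@dataclass(frozen=True)
class ShlGrid:
    """Half-integer contact SHLs and the integer defect SHLs between them.

    The strong histone-DNA contact points sit at the 14 half-integer SHLs;
    twist defects accumulate at the 13 integer SHLs, each flanked by the
    contacts at ``i - 0.5`` and ``i + 0.5``.
    """

    contact_shls: np.ndarray = field(
        default_factory=lambda: np.arange(-6.5, 7.0, 1.0)
    )
    defect_shls: np.ndarray = field(
        default_factory=lambda: np.arange(-6.0, 7.0, 1.0)
    )

    def __post_init__(self) -> None:
        c, d = np.asarray(self.contact_shls), np.asarray(self.defect_shls)
        if not (np.allclose(np.diff(c), 1.0) and np.allclose(np.diff(d), 1.0)):
            raise ValueError("SHL grids must be strictly increasing with unit spacing")
        if len(c) != len(d) + 1:
            raise ValueError("need one more contact than defect site")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_shls)

    @property
    def n_defects(self) -> int:
        return len(self.defect_shls)

    def contact_index(self, shl: float) -> int:
        """Array index of the contact at half-integer SHL ``shl``."""
        idx = int(round(shl - self.contact_shls[0]))
        if not np.isclose(self.contact_shls[idx], shl):
            raise KeyError(f"no contact at SHL {shl}")
        return idx

    def defect_index(self, shl: int) -> int:
        idx = int(round(shl - self.defect_shls[0]))
        if not np.isclose(self.defect_shls[idx], shl):
            raise KeyError(f"no defect site at SHL {shl}")
        return idx


GRID = ShlGrid()

# frequently used contact indices on the default grid
IX_M15 = GRID.contact_index(-1.5)
IX_P05 = GRID.contact_index(0.5)
IX_P15 = GRID.contact_index(1.5)
IX_P25 = GRID.contact_index(2.5)


@dataclass
class SystemState:
    """One configuration of the 16 reduced coordinates."""

    x: np.ndarray  # (14,) contact indexes, bp
    y1: float = 0.0  # lobe-1 contact index, bp
    y2: float = 0.0  # lobe-2 contact index, bp

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (GRID.n_contacts,):
            raise ValueError(f"x must have shape ({GRID.n_contacts},)")
        if not (np.all(np.isfinite(self.x)) and np.isfinite(self.y1) and np.isfinite(self.y2)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def zeros(cls) -> "SystemState":
        return cls(x=np.zeros(GRID.n_contacts))

    def defects(self) -> np.ndarray:
        """Twist defects d_i = x_{i+0.5} - x_{i-0.5} at the 13 integer SHLs."""
        return np.diff(self.x)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.x, [self.y1, self.y2]])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "SystemState":
        v = np.asarray(v, dtype=float)
        return cls(x=v[:-2].copy(), y1=float(v[-2]), y2=float(v[-1]))


@dataclass(frozen=True)
class DefectSiteParams:
    """Twist-defect energetics at one integer SHL.

    k is the twist stiffness (kT/bp^2) of the harmonic branches around the
    d = -1, 0, +1 wells; mu_plus / mu_minus are the free-energy penalties (kT)
    of the +1 bp and -1 bp defect wells relative to the defect-free state.
    """

    k: float
    mu_plus: float
    mu_minus: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("twist stiffness must be positive")
        if self.mu_plus < 0 or self.mu_minus < 0:
            raise ValueError("defect penalties must be non-negative")


@dataclass(frozen=True)
class ContactParams:
    """Histone-DNA contact energetics at one half-integer SHL.

    ``depth`` sets the barrier of the 1-bp periodic well; ``flank`` adds a
    second-harmonic term that steepens the well walls without changing the
    barrier top (it vanishes at half-integer displacements), penalizing
    partial, distributed DNA displacement as a sharp hydrogen-bond contact
    does; ``tilt`` is the linear positioning bias of strong positioning
    sequences."""

    depth: float
    tilt: float = 0.0
    flank: float = 1.6

    def __post_init__(self) -> None:
        if self.depth < 0 or self.flank < 0:
            raise ValueError("contact well depth and flank must be non-negative")


@dataclass(frozen=True)
class RemodelerParams:
    """Chemical-state-independent base parameters of the translocase.

    eps_lobe_dna
        apo-state grip well depth of each lobe on DNA (kT).
    eps_lobes
        lobe-lobe coupling per chemical state (kT); the ATP value drives
        closure, apo/ADP values leave the open form preferred.
    adp_lobe2_factor, adp_lobe1_factor
        multiplicative weakening of the lobe grips after hydrolysis; the
        opening conformational change strains both lobe-DNA interfaces,
        lobe 2 distinctly more, which sets the direction of opening.
    grip_contacts
        effective number of simultaneously engaged DNA contacts per lobe;
        the grip well depth seen by the dynamics is grip_contacts times the
        per-contact strength eps_lobe_dna.
    lobe1_strain
        ATP-state destabilization of the unadvanced lobe-1 register (kT);
        models the strained lobe 1-DNA interface of the closed conformation.
    defect_relief, twist_softening, contact_relief
        ATP-state distortion of the DNA at the binding site: the +1 bp
        defect penalty at SHL +1 and the -1 bp penalty at SHL +2 are reduced
        by ``defect_relief`` (kT), the twist stiffness at those SHLs is
        multiplied by ``twist_softening``, and the histone-DNA contact wells
        at SHL 1.5 and 2.5 are shallowed by ``contact_relief`` (kT): the
        closed translocase stabilizes the opposite-type defect pair that
        initiates sliding.
    closure_offset
        conformational cost of the closed form (kT); closure is favorable
        only when the state's lobe coupling exceeds it.
    closure_barrier
        barrier height (kT) of the open/closed conformational double well.
    eps_elec, elec_width
        depth (kT) and range (bp) of the electrostatic spring between the
        lobe-1 basic patch and the distal DNA gyre; the mutant remodeler
        (charge-reversed patch) has eps_elec = 0.
    wall_halfwidth, wall_height
        flat-bottom steric wall limiting the excursion of the remodeler body
        relative to the DNA at its binding site (bp, kT).
    """

    eps_lobe_dna: tuple[float, float] = (1.8, 1.8)
    eps_lobes: dict = field(
        default_factory=lambda: {
            ChemicalState.APO: 0.17,
            ChemicalState.ATP: 1.0,
            ChemicalState.ADP: 0.17,
        }
    )
    adp_lobe2_factor: float = 0.8
    adp_lobe1_factor: float = 0.80
    grip_contacts: float = 4.8
    lobe1_strain: float = 17.2
    defect_relief: float = 5.1
    twist_softening: float = 0.5
    contact_relief: float = 2.0
    closure_offset: float = 5.2
    closure_barrier: float = 1.5
    eps_elec: float = 6.4
    elec_width: float = 0.35
    wall_halfwidth: float = 0.3
    wall_height: float = 50.0

    def __post_init__(self) -> None:
        if min(self.eps_lobe_dna) < 0 or self.eps_elec < 0 or self.wall_height < 0:
            raise ValueError("interaction depths must be non-negative")
        if any(v < 0 for v in self.eps_lobes.values()):
            raise ValueError("lobe coupling must be non-negative")

    def mutant(self) -> "RemodelerParams":
        """Charge-mutant remodeler: electrostatic spring switched off."""
        return replace(self, eps_elec=0.0)


@dataclass
class SequenceProfile:
    """Per-site energetic parameters derived from a DNA sequence.

    One DefectSiteParams per integer SHL, one ContactParams per half-integer
    SHL, plus the lobe-grip multipliers g1, g2 set by the sequence under the
    translocase binding site.
    """

    defect_sites: list  # [DefectSiteParams] * 13
    contacts: list  # [ContactParams] * 14
    g1: float = 1.0
    g2: float = 1.0

    def __post_init__(self) -> None:
        if len(self.defect_sites) != GRID.n_defects:
            raise ValueError("one DefectSiteParams per defect SHL required")
        if len(self.contacts) != GRID.n_contacts:
            raise ValueError("one ContactParams per contact SHL required")
        for g in (self.g1, self.g2):
            if not 0.0 < g <= 2.0:
                raise ValueError("lobe-grip multipliers must be in (0, 2]")

    @classmethod
    def uniform(
        cls,
        depth: float = 2.0,
        k: float = 15.0,
        mu_plus: float = 5.8,
        mu_minus: float = 5.8,
        mu_outer: float = 2.8,
        outer_depth: float = 0.5,
        tilt: float = 0.0,
        flank: float = 2.4,
        outer_flank: float = 0.6,
    ) -> "SequenceProfile":
        sites = [
            DefectSiteParams(
                k,
                mu_plus if abs(shl) <= 2 else mu_outer,
                mu_minus if abs(shl) <= 2 else mu_outer,
            )
            for shl in GRID.defect_shls
        ]
        contacts = [
            ContactParams(depth if abs(shl) < 3.0 else outer_depth, tilt,
                          flank if abs(shl) < 3.0 else outer_flank)
            for shl in GRID.contact_shls
        ]
        return cls(defect_sites=sites, contacts=contacts)

    # convenient dense views used by the energy kernels
    def arrays(self) -> dict:
        return {
            "k": np.array([p.k for p in self.defect_sites]),
            "mu_plus": np.array([p.mu_plus for p in self.defect_sites]),
            "mu_minus": np.array([p.mu_minus for p in self.defect_sites]),
            "depth": np.array([c.depth for c in self.contacts]),
            "tilt": np.array([c.tilt for c in self.contacts]),
            "flank": np.array([c.flank for c in self.contacts]),
        }


@dataclass(frozen=True)
class ParameterSet:
    """Fully resolved numeric parameters for one chemical state.

    A deterministic function of (RemodelerParams, SequenceProfile,
    ChemicalState); this is what the energy and dynamics kernels consume.
    """

    chem: ChemicalState
    contact_depth: np.ndarray  # (14,)
    contact_flank: np.ndarray  # (14,)
    tilt: np.ndarray  # (14,)
    twist_k: np.ndarray  # (13,)
    twist_mu_plus: np.ndarray  # (13,)
    twist_mu_minus: np.ndarray  # (13,)
    grip1: float
    grip2: float
    grip_mult: float  # effective contacts per lobe; well depth = grip_mult * grip
    lobe_coupling: float
    closure_offset: float
    closure_barrier: float
    lobe1_strain: float
    eps_elec: float
    elec_width: float
    wall_halfwidth: float
    wall_height: float
    smoothing: float = 0.2  # kT, log-sum-exp smoothing of the twist wells
    naked: bool = False  # True: DNA-octamer terms inactive (bare-DNA mode)
    y_anchor: float = 0.0  # cycle-start lobe-1 registration (bp); the ATP
    # strain and the closure gating are measured from here

    def digest(self) -> str:
        """Short stable hash of all numeric content (trajectory metadata)."""
        payload = {
            "chem": self.chem.value,
            "naked": self.naked,
            "arrays": [
                np.round(np.asarray(a), 12).tolist()
                for a in (
                    self.contact_depth,
                    self.contact_flank,
                    self.tilt,
                    self.twist_k,
                    self.twist_mu_plus,
                    self.twist_mu_minus,
                )
            ],
            "scalars": [
                self.grip1, self.grip2, self.grip_mult, self.lobe_coupling, self.closure_offset,
                self.closure_barrier, self.lobe1_strain, self.eps_elec,
                self.elec_width, self.wall_halfwidth, self.wall_height,
                self.smoothing, self.y_anchor,
            ],
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


def effective_params(
    base: RemodelerParams,
    seq: SequenceProfile,
    chem: ChemicalState,
    naked: bool = False,
) -> ParameterSet:
    """Resolve the parameters active in chemical state ``chem``.

    apo: grips at their base depths (times the sequence multipliers), weak
    lobe coupling, no strain.  ATP: lobe coupling raised to its ATP value,
    the lobe-1 strain switched on (grip depths unchanged) and the defect
    penalties at the binding site relieved (+1 bp at SHL +1, -1 bp at
    SHL +2).  ADP: the lobe-2 grip is weakened by ``adp_lobe2_factor`` and
    the coupling reverts to the apo value.
    """
    if not isinstance(chem, ChemicalState):
        raise TypeError(f"unknown chemical state: {chem!r}")
    arr = seq.arrays()
    eps1, eps2 = base.eps_lobe_dna
    grip1 = eps1 * seq.g1
    grip2 = eps2 * seq.g2
    strain = 0.0
    if chem is ChemicalState.ADP:
        grip1 *= base.adp_lobe1_factor
        grip2 *= base.adp_lobe2_factor
    elif chem is ChemicalState.ATP:
        strain = base.lobe1_strain
        if not naked:
            mp = arr["mu_plus"].copy()
            mm = arr["mu_minus"].copy()
            kk = arr["k"].copy()
            dep = arr["depth"].copy()
            i1, i2 = GRID.defect_index(1), GRID.defect_index(2)
            mp[i1] = max(0.0, mp[i1] - base.defect_relief)
            mm[i2] = max(0.0, mm[i2] - base.defect_relief)
            kk[i1] *= base.twist_softening
            kk[i2] *= base.twist_softening
            dep[IX_P15] = max(0.0, dep[IX_P15] - base.contact_relief)
            dep[IX_P25] = max(0.0, dep[IX_P25] - base.contact_relief)
            flk = arr["flank"].copy()
            flk[IX_P15] = 0.0  # the engaged translocase pre-distorts its
            flk[IX_P25] = 0.0  # site contacts; their steep flanks vanish
            arr["mu_plus"], arr["mu_minus"] = mp, mm
            arr["k"], arr["depth"], arr["flank"] = kk, dep, flk
    return ParameterSet(
        chem=chem,
        contact_depth=arr["depth"],
        contact_flank=arr["flank"],
        tilt=arr["tilt"],
        twist_k=arr["k"],
        twist_mu_plus=arr["mu_plus"],
        twist_mu_minus=arr["mu_minus"],
        grip1=grip1,
        grip2=grip2,
        grip_mult=base.grip_contacts,
        lobe_coupling=base.eps_lobes[chem],
        closure_offset=base.closure_offset,
        closure_barrier=base.closure_barrier,
        lobe1_strain=strain,
        eps_elec=base.eps_elec,
        elec_width=base.elec_width,
        wall_halfwidth=base.wall_halfwidth,
        wall_height=base.wall_height,
        naked=naked,
    )
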
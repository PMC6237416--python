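"""DNA sequences and their mapping to twist-defect energetics.

The reference sequence is polyApG ("AG" repeated), a uniform 2-bp-periodic
sequence of intermediate nucleosomal flexibility.  Sequence elements are
10-bp tracts replacing the window centered at a chosen superhelical
location: poly(dA:dT) ("AA" x 5) stiffens DNA and penalizes +1 bp defects;
TpA repeats ("TA" x 5) at |SHL| = 2 penalize -1 bp defects there and weaken
the lobe-2 grip.  Strong positioning (601-like) is modeled phenomenologically
as a linear tilt toward the preferred register, applied at the contacts
flanking the remodeler site, rather than base by base.

SHL n maps to base-pair offset 10 n from the dyad.  The reduced model has
no helical phase, so the integer 10 bp/SHL convention is used instead of
the crystallographic ~10.17.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GRID,
    ContactParams,
    DefectSiteParams,
    SequenceProfile,
)

__all__ = [
    "BaseSequence",
    "MappingRules",
    "build_sequence",
    "profile_from_sequence",
    "read_fasta",
    "write_fasta",
]

BP_PER_SHL = 10
WRAP_HALF = 73  # bp of wrapped DNA on each side of the dyad


@dataclass(frozen=True)
class BaseSequence:
    """A nucleosomal DNA sequence with a declared dyad position."""

    seq: str
    dyad: int
    name: str = "seq"
    positioning_tilt: float = 0.0  # kT/bp toward the pre-shift register

    def __post_init__(self) -> None:
        bad = [i for i, b in enumerate(self.seq) if b not in "ACGT"]
        if bad:
            raise ValueError(f"non-ACGT character at position {bad[0]}")
        if not 0 <= self.dyad < len(self.seq):
            raise ValueError("dyad index outside sequence")

    def window(self, shl: float, width: int = 10) -> str:
        """The ``width`` bp centered at dyad + 10*shl (start offset
        10*shl - width//2)."""
        start = self.dyad + BP_PER_SHL * round(shl) - width // 2
        if start < 0 or start + width > len(self.seq):
            raise ValueError(f"window at SHL {shl} outside sequence")
        return self.seq[start : start + width]


@dataclass(frozen=True)
class MappingRules:
    """Sequence-to-energetics rules.

    Baselines give the uniform polyApG parameters; increments fire only at
    element-occupied SHLs.  All values are calibration products of the
    reduced model and config-overridable.
    """

    baseline_depth: float = 2.0  # central contact well depth (|SHL| < 3), kT
    baseline_flank: float = 2.4  # central contact flank steepening, kT
    outer_depth: float = 0.5  # outer contact well depth (|SHL| > 3), kT
    outer_flank: float = 0.6  # outer contact flank steepening, kT
    baseline_k: float = 15.0  # twist stiffness, kT/bp^2
    baseline_mu: float = 5.8  # defect penalty at the central SHLs (|SHL| <= 2), kT
    baseline_mu_outer: float = 2.8  # defect penalty at the outer SHLs (|SHL| >= 3), kT
    d_mu_plus_apa: float = 2.0  # ApA tract: extra +1 bp penalty, kT
    d_mu_minus_tpa: float = 3.5  # TpA at |SHL|=2: extra -1 bp penalty, kT
    k_mult_tpa: float = 0.7  # TpA flexibility: twist-stiffness multiplier
    g2_tpa: float = 0.10  # TpA at SHL 2: lobe-2 grip multiplier
    tilt_601: float = 2.9  # positioning tilt magnitude, kT/bp
    mirror: bool = False  # also apply element rules at the mirrored -SHL


def build_sequence(kind: str, length: int = 2 * WRAP_HALF + 1, element_shl: int = 2) -> BaseSequence:
    """Construct one of the study sequences.

    kind: 'polyApG'; 'polyApG-ApA' / 'polyApG-TpA' (10-bp element replacing
    the window at ``element_shl``); '601' (polyApG backbone flagged with the
    positioning tilt, representing a strong positioning sequence started
    3 bp off its optimal register).
    """
    backbone = ("AG" * (length // 2 + 1))[:length]
    dyad = length // 2
    if kind == "polyApG":
        return BaseSequence(backbone, dyad, name="polyApG")
    if kind in ("polyApG-ApA", "polyApG-TpA"):
        unit = "AA" if kind.endswith("ApA") else "TA"
        start = dyad + BP_PER_SHL * element_shl - 5
        if start < dyad - WRAP_HALF or start + 10 > dyad + WRAP_HALF + 1:
            raise ValueError(f"element at SHL {element_shl} outside the wrapped region")
        s = backbone[:start] + unit * 5 + backbone[start + 10 :]
        return BaseSequence(s, dyad, name=f"{kind}_SHL{element_shl}")
    if kind == "601":
        return BaseSequence(backbone, dyad, name="601_d3", positioning_tilt=1.0)
    raise ValueError(f"unknown sequence kind {kind!r}")


def _element_at(seq: BaseSequence, shl: int) -> str | None:
    """'ApA'/'TpA' if the 10-bp window at integer SHL shl is that element."""
    try:
        w = seq.window(shl)
    except ValueError:
        return None
    if w == "AA" * 5:
        return "ApA"
    if w in ("TA" * 5, "AT" * 5):
        return "TpA"
    return None


def profile_from_sequence(seq: BaseSequence, rules: MappingRules | None = None) -> SequenceProfile:
    """Derive per-site energetic parameters from a sequence.

    polyApG windows produce the uniform baseline everywhere.  An ApA window
    raises the +1 bp penalty at its SHL; a TpA window softens the twist
    stiffness there and, at |SHL| = 2, raises the -1 bp penalty; a TpA
    element at SHL +2 (under the translocase) additionally weakens the
    lobe-2 grip.  A positioning flag adds the tilt at contacts 1.5 and 2.5,
    half each.
    """
    rules = rules or MappingRules()
    sites = []
    g2 = 1.0
    for shl in GRID.defect_shls:
        shl = int(shl)
        mu = rules.baseline_mu if abs(shl) <= 2 else rules.baseline_mu_outer
        p = DefectSiteParams(rules.baseline_k, mu, mu)
        elem = _element_at(seq, shl)
        if elem is None and rules.mirror:
            elem = _element_at(seq, -shl)
        if elem == "ApA":
            p = replace(p, mu_plus=p.mu_plus + rules.d_mu_plus_apa)
        elif elem == "TpA":
            p = replace(p, k=p.k * rules.k_mult_tpa)
            if abs(shl) == 2:
                p = replace(p, mu_minus=p.mu_minus + rules.d_mu_minus_tpa)
        sites.append(p)
        if shl == 2 and elem == "TpA":
            g2 = rules.g2_tpa
    tilt_each = 0.5 * seq.positioning_tilt * rules.tilt_601
    contacts = []
    for shl in GRID.contact_shls:
        t = tilt_each if abs(shl - 2.0) < 0.6 else 0.0  # contacts 1.5 and 2.5
        if abs(shl) < 3.0:
            contacts.append(ContactParams(rules.baseline_depth, t, rules.baseline_flank))
        else:
            contacts.append(ContactParams(rules.outer_depth, t, rules.outer_flank))
    return SequenceProfile(defect_sites=sites, contacts=contacts, g2=g2)


def read_fasta(path) -> BaseSequence:
    """Read a single-record FASTA; lowercase is normalized to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    s = str(rec.seq).upper()
    dyad = len(s) // 2
    for tok in rec.description.split():
        if tok.startswith("dyad="):
            dyad = int(tok[5:])
    return BaseSequence(s, dyad=dyad, name=rec.id)


def write_fasta(seq: BaseSequence, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq.seq), id=seq.name, description=f"dyad={seq.dyad}")],
        str(path),
        "fasta",
    )
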
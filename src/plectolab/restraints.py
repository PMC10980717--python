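"""Generator for the tension/torsion restraint specification used to
hold a linear DNA duplex at fixed force and supercoiling density in an
all-atom simulation.

The construct is core duplex + a GC buffer at the mobile end (held
straight so excluded-volume restraints trigger rarely) + 2 GC bp at the
fixed end.  Restraints emitted:

* positional restraints pinning O3'/O5' of the final fixed-end bp;
* one linear distance restraint per strand pulling the mobile-end
  O3'/O5' toward fixed reference points A and B, with slope set so the
  restraint force equals the requested tension per strand;
* angle pairs (theta1, theta2) per lateral axis confining mobile-end
  motion to the tether axis;
* one psi >= 90 degree angle restraint per bulk phosphorus and per
  strand end — an excluded volume resembling a bead, preventing the
  chain passing over either end and untying its supercoiling;
* anti-bending dihedrals, one per complementary phosphorus pair of the
  buffer;
* two torsional coplanarity dihedrals (first mobile core bp and
  next-to-last fixed bp against the reference points) that lock the
  linking difference in.

Only the specification is produced; no simulation is run.  Records are
written as AMBER-style NMR restraint (RST) text and as neutral JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RestraintRecord", "RestraintSpec", "gen_torsion_restraints"]

#: kcal/(mol*A) per pN of restraint force slope.
PN_TO_KCAL_PER_MOL_A = 0.014393

#: Reference/dummy point names: A,B pull targets; E,F and I,J define
#: the coplanarity dihedral planes at the mobile and fixed ends.
REFERENCE_POINTS = ("A", "B", "E", "F", "I", "J")


@dataclass
class RestraintRecord:
    kind: str                   # positional | distance | angle | dihedral
    atoms: list                 # (residue index, atom name) or point name
    target: float               # A or degrees
    lower: float
    upper: float
    force_constant: float       # kcal/mol/A^2 (or /rad^2); linear slope
    comment: str = ""

    def resolve(self, n_bp: int) -> bool:
        """Every atom selector must reference a residue inside the
        duplex (1..2*n_bp over both strands) or a reference point."""
        for a in self.atoms:
            if isinstance(a, str):
                if a not in REFERENCE_POINTS:
                    return False
            else:
                res, name = a
                if not (1 <= res <= 2 * n_bp):
                    return False
                if name not in ("O3'", "O5'", "P"):
                    return False
        return True


@dataclass
class RestraintSpec:
    records: list[RestraintRecord]
    sequence: str
    core_bp: int
    buffer_gc_bp: int
    fixed_gc_bp: int
    force_pN: float
    sigma: float
    reference_standoff_A: float = 20.0

    @property
    def total_bp(self) -> int:
        return len(self.sequence)

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.kind] = out.get(r.kind, 0) + 1
        return out

    def validate(self) -> None:
        n = self.total_bp
        for r in self.records:
            if not r.resolve(n):
                raise ValueError(f"unresolvable record: {r}")
            if r.kind == "angle" and "psi" in r.comment and r.lower != 90.0:
                raise ValueError("psi records must have lower bound 90")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "sequence": self.sequence, "core_bp": self.core_bp,
            "buffer_gc_bp": self.buffer_gc_bp,
            "fixed_gc_bp": self.fixed_gc_bp,
            "force_pN": self.force_pN, "sigma": self.sigma,
            "records": [vars(r) for r in self.records]}, indent=1))

    def to_rst(self, path) -> None:
        """AMBER NMR-restraint text.  Reference points are written as
        dummy-atom placeholders (iat = -1 with igr comments) because
        their indices depend on how the topology numbers dummies."""
        lines = []
        for r in self.records:
            sel = ", ".join(
                a if isinstance(a, str) else f"res {a[0]} {a[1]}"
                for a in r.atoms)
            lines.append(f"# {r.kind}: {sel}  ({r.comment})")
            lines.append("&rst iat=-1,")
            lines.append(f"  r1={r.lower - 1.0:.2f}, r2={r.lower:.2f}, "
                         f"r3={r.upper:.2f}, r4={r.upper + 1.0:.2f},")
            lines.append(f"  rk2={r.force_constant:.5f}, "
                         f"rk3={r.force_constant:.5f}, /")
        Path(path).write_text("\n".join(lines) + "\n")


def gen_torsion_restraints(core_bp: int, force_pN: float, sigma: float,
                           core_sequence: str | None = None,
                           buffer_gc_bp: int = 60, fixed_gc_bp: int = 2,
                           positional_k: float = 25.0,
                           angle_k: float = 50.0,
                           dihedral_k: float = 50.0,
                           reference_standoff_A: float = 20.0,
                           ) -> RestraintSpec:
    """Emit the full restraint specification plus construct sequence.

    Residues are numbered 1..L on strand 1 (fixed end = residue L) and
    L+1..2L on strand 2; the reference points sit on the tether axis at
    `reference_standoff_A` beyond the mobile end (a recorded choice —
    their exact placement only needs to be axial).
    """
    if core_bp < 50:
        raise ValueError("core must be >= 50 bp")
    if force_pN < 0:
        raise ValueError("force must be >= 0")
    if abs(sigma) > 0.2:
        raise ValueError("|sigma| must be <= 0.2")
    if core_sequence is not None and len(core_sequence) != core_bp:
        raise ValueError("core_sequence length != core_bp")
    core = core_sequence or ("GC" * ((core_bp + 1) // 2))[:core_bp]
    buffer_seq = ("GC" * ((buffer_gc_bp + 1) // 2))[:buffer_gc_bp]
    fixed_seq = ("GC" * ((fixed_gc_bp + 1) // 2))[:fixed_gc_bp]
    # strand 1, 5'->3', mobile end first: buffer | core | fixed end
    seq = buffer_seq + core + fixed_seq
    L = len(seq)
    recs: list[RestraintRecord] = []
    dist_k = PN_TO_KCAL_PER_MOL_A * force_pN

    # (i) fixed-end positional restraints: O3'/O5' of the final bp,
    # both strands
    for res in (L, L + 1):          # strand1 3' end, strand2 5' end
        for atom in ("O3'", "O5'"):
            recs.append(RestraintRecord(
                "positional", [(res, atom)], 0.0, 0.0, 0.0, positional_k,
                comment="fixed-end anchor"))

    # (ii) linear distance restraints to reference points A and B,
    # slope = requested force per strand
    recs.append(RestraintRecord(
        "distance", [(1, "O5'"), "A"], reference_standoff_A, 0.0,
        reference_standoff_A, dist_k, comment="tension strand 1"))
    recs.append(RestraintRecord(
        "distance", [(2 * L, "O3'"), "B"], reference_standoff_A, 0.0,
        reference_standoff_A, dist_k, comment="tension strand 2"))

    # (iii) angle pairs confining mobile-end motion to the tether axis:
    # theta1/theta2 per lateral axis (y via A-B, x via the second pair)
    for axis, pts in (("y", ("A", "B")), ("x", ("E", "F"))):
        for i, theta in enumerate(("theta1", "theta2")):
            recs.append(RestraintRecord(
                "angle", [(1 if i == 0 else 2 * L, "O5'" if i == 0
                           else "O3'"), pts[0], pts[1]],
                90.0, 80.0, 100.0, angle_k,
                comment=f"{theta} axial confinement ({axis})"))

    # (iv) psi >= 90 deg excluded-volume records: one per phosphorus of
    # the bulk of each strand and one per strand end
    for strand, (lo, hi) in ((1, (2, L)), (2, (L + 2, 2 * L))):
        end_res = 1 if strand == 1 else L + 1
        end_atom = "O5'" if strand == 1 else "O3'"
        ref = "A" if strand == 1 else "B"
        for res in range(lo, hi + 1):
            recs.append(RestraintRecord(
                "angle", [(res, "P"), (end_res, end_atom), ref],
                120.0, 90.0, 180.0, angle_k,
                comment="psi excluded volume"))
        recs.append(RestraintRecord(
            "angle", [(end_res, end_atom), (lo, "P"), ref],
            120.0, 90.0, 180.0, angle_k, comment="psi end excluded volume"))

    # (v) buffer anti-bending dihedrals: one per complementary
    # phosphorus pair of the buffer stretch
    for i in range(1, buffer_gc_bp + 1):
        recs.append(RestraintRecord(
            "dihedral", [(i, "P"), (2 * L + 1 - i, "P"), "A", "B"],
            0.0, -10.0, 10.0, dihedral_k, comment="buffer anti-bending"))

    # (vi) torsional coplanarity dihedrals: first core bp at the
    # mobile side (bp index buffer+1) and next-to-last fixed-end bp
    mob = buffer_gc_bp + 1
    recs.append(RestraintRecord(
        "dihedral", [(mob, "O3'"), (2 * L + 1 - mob, "O5'"), "A", "B"],
        0.0, -5.0, 5.0, dihedral_k,
        comment="torsion lock mobile (planes ABF/BAE)"))
    recs.append(RestraintRecord(
        "dihedral", [(L - 1, "O3'"), (L + 2, "O5'"), "I", "J"],
        0.0, -5.0, 5.0, dihedral_k, comment="torsion lock fixed"))

    spec = RestraintSpec(records=recs, sequence=seq, core_bp=core_bp,
                         buffer_gc_bp=buffer_gc_bp,
                         fixed_gc_bp=fixed_gc_bp, force_pN=force_pN,
                         sigma=sigma,
                         reference_standoff_A=reference_standoff_A)
    spec.validate()
    return spec
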
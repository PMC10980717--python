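"""Sequence-based prediction of denaturation-bubble and plectoneme
sites.

Two per-bp profiles are produced from a DNA sequence:

* an opening (melting-bubble) probability profile from an equilibrium
  statistical-mechanical model of stress-induced duplex destabilization
  under negative superhelicity (SIDD-type): states are at most
  `max_runs` contiguous open runs; a state pays an initiation cost per
  run, per-bp strand-separation energies, and a quadratic
  residual-superhelicity term, with the linking difference partitioned
  between open-region untwisting, interstrand winding of the open
  strands, and residual stress;

* a plectoneme-centre probability profile driven by intrinsic DNA
  curvature: the bending energy of the plectoneme tip loop is reduced
  where static curvature already bends the helix, so tip placement is
  Boltzmann-weighted by the local curvature, averaged over plectoneme
  sizes up to a supercoiling-regime-dependent cutoff.

Intrinsic curvature uses the dinucleotide wedge model of Bolshoy et
al., PNAS 88:2312 (1991) (twist/wedge/direction per step); opening
energetics follow Benham's superhelical-destabilization treatment
(e.g. Benham, J. Mol. Biol. 225:835 (1992); Bi & Benham,
Bioinformatics 20:1477 (2004)).  Profiles are intended to be read
relatively (peak positions), decoupling conclusions from the exact
parameter tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .constants import HELICAL_REPEAT_BP, RISE_NM_PER_BP, kbt

__all__ = [
    "SequenceRecord", "OpeningProfile", "PlectonemeProfile",
    "WEDGE_TABLE", "intrinsic_curvature", "plectoneme_probability",
    "sidd_profile", "expected_bubble_size", "compare_profiles",
    "default_size_cutoff_bp",
]

#: Dinucleotide step parameters (twist, wedge, direction), degrees,
#: from Bolshoy et al., PNAS 88:2312 (1991).
WEDGE_TABLE = {
    "AA": (35.62, 7.2, -154.0), "AC": (34.40, 1.1, 143.0),
    "AG": (27.70, 8.4, 2.0),    "AT": (31.50, 2.6, 0.0),
    "CA": (34.50, 3.5, -64.0),  "CC": (33.67, 2.1, -57.0),
    "CG": (29.80, 6.7, 0.0),    "CT": (27.70, 8.4, -2.0),
    "GA": (36.90, 5.3, 120.0),  "GC": (40.00, 5.0, 180.0),
    "GG": (33.67, 2.1, 57.0),   "GT": (34.40, 1.1, -143.0),
    "TA": (36.00, 0.9, 0.0),    "TC": (36.90, 5.3, -120.0),
    "TG": (34.50, 3.5, 64.0),   "TT": (35.62, 7.2, 154.0),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987204e-3


@dataclass
class SequenceRecord:
    """A DNA sequence with 1-based inclusive coordinates."""

    identifier: str
    sequence: str

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {bad}")

    def __len__(self):
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path) -> "SequenceRecord":
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(rec.id, str(rec.seq))

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.identifier + "_rc",
                              self.sequence.translate(_COMPLEMENT)[::-1])


@dataclass
class OpeningProfile:
    """Per-bp probability of lying inside a denatured run."""

    probabilities: np.ndarray
    sigma: float
    salt_M: float
    temperature_K: float
    params: dict
    run_length_weights: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, float)
        if np.any((self.probabilities < -1e-12)
                  | (self.probabilities > 1 + 1e-12)):
            raise ValueError("opening probabilities must lie in [0, 1]")


@dataclass
class PlectonemeProfile:
    """Per-bp probability density of hosting a plectoneme centre
    (tip); normalised to sum to 1 over the sequence."""

    density: np.ndarray
    sigma: float
    size_cutoff_bp: int

    def __post_init__(self):
        self.density = np.asarray(self.density, float)
        s = self.density.sum()
        if s > 0 and abs(s - 1.0) > 1e-6:
            raise ValueError("plectoneme density must be normalised")


def _seq_str(seq) -> str:
    if isinstance(seq, SequenceRecord):
        return seq.sequence
    return SequenceRecord("_", str(seq)).sequence


def _step_vectors(s: str) -> np.ndarray:
    """Lab-frame 2-D deflection vector per dinucleotide step: wedge
    magnitude at the helically rotated direction angle.  The wedge is
    applied at the mid-step phase (half the step twist before, half
    after), which makes the windowed curvature magnitude invariant
    under reverse complementation."""
    n = len(s) - 1
    out = np.empty((n, 2))
    phase = 0.0
    for i in range(n):
        tw, wedge, direc = WEDGE_TABLE[s[i:i + 2]]
        ang = math.radians(phase + tw / 2.0 + direc)
        out[i] = wedge * math.cos(ang), wedge * math.sin(ang)
        phase += tw
    return out


def intrinsic_curvature(seq, window_bp: int = 63) -> np.ndarray:
    """Static curvature profile, degrees per helical turn.

    Dinucleotide-step deflection vectors (wedge model) are summed in
    the lab frame over a sliding window; the magnitude of the vector
    sum, rescaled to one helical repeat, is assigned to the window
    centre.  Ends are padded with the nearest interior value so the
    profile has one entry per bp.
    """
    s = _seq_str(seq)
    if window_bp < 10:
        raise ValueError("window must be >= 10 bp")
    if len(s) < window_bp + 1:
        raise ValueError("sequence shorter than the window")
    vec = _step_vectors(s)
    cum = np.vstack([np.zeros(2), np.cumsum(vec, axis=0)])
    n_win = vec.shape[0] - window_bp + 1
    sums = cum[window_bp:window_bp + n_win] - cum[:n_win]
    mag = np.hypot(sums[:, 0], sums[:, 1])
    mag *= HELICAL_REPEAT_BP / window_bp
    prof = np.empty(len(s))
    start = window_bp // 2
    prof[start:start + n_win] = mag
    prof[:start] = mag[0]
    prof[start + n_win:] = mag[-1]
    return prof


def default_size_cutoff_bp(sigma: float) -> int:
    """Largest plectoneme size admitted when averaging tip placement,
    by supercoiling regime (established from experimental estimates of
    plectoneme bp content): 8300 bp for sigma >= 0.12, 6700 bp for
    0.08 <= sigma < 0.12, 1900 bp for negative sigma."""
    if sigma >= 0.12:
        return 8300
    if sigma >= 0.08:
        return 6700
    if sigma < 0:
        return 1900
    return 1000


def plectoneme_probability(seq, sigma: float,
                           size_cutoff_bp: int | None = None,
                           tip_loop_bp: int = 75,
                           persistence_length_nm: float = 50.0,
                           temperature_K: float = 310.0,
                           curvature_window_bp: int = 63,
                           ) -> PlectonemeProfile:
    """Curvature-driven probability density of plectoneme tip
    placement.

    The tip loop (default 75 bp) must bend through a full circle; the
    elastic cost is (kB*T*P/2) * l * (kappa_loop - kappa_local)^2 with
    kappa_loop = 2*pi/l and kappa_local the static curvature, so
    intrinsically curved sites are cheaper tips.  The density at each
    bp is the Boltzmann weight averaged over plectoneme sizes from the
    tip loop up to `size_cutoff_bp` that fit inside the sequence, then
    normalised.
    """
    s = _seq_str(seq)
    n = len(s)
    if size_cutoff_bp is None:
        size_cutoff_bp = default_size_cutoff_bp(sigma)
    if size_cutoff_bp >= n:
        raise ValueError("size cutoff must be smaller than the sequence")
    curv = intrinsic_curvature(s, curvature_window_bp)   # deg per turn
    # degrees/turn -> rad/nm
    kappa_local = np.radians(curv) / (HELICAL_REPEAT_BP * RISE_NM_PER_BP)
    l_nm = tip_loop_bp * RISE_NM_PER_BP
    kappa_loop = 2.0 * math.pi / l_nm
    bend = np.maximum(kappa_loop - kappa_local, 0.0)
    E_tip = 0.5 * kbt(temperature_K) * persistence_length_nm * l_nm \
        * bend ** 2
    w = np.exp(-(E_tip - E_tip.min()) / kbt(temperature_K))
    # average over plectoneme sizes that fit around each centre; sizes
    # share the same tip energy, so this only zeroes centres where not
    # even the smallest plectoneme fits
    idx = np.arange(n)
    half_min = tip_loop_bp // 2
    fits = (idx >= half_min) & (idx < n - half_min)
    w = np.where(fits, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no admissible plectoneme centre")
    return PlectonemeProfile(density=w / total, sigma=sigma,
                             size_cutoff_bp=int(size_cutoff_bp))


# ---------------------------------------------------------------------------
# SIDD-type opening profile
# ---------------------------------------------------------------------------

#: Copolymeric strand-separation energies (kcal/mol per bp) near 310 K
#: and 0.1 M salt, and the run initiation cost (kcal/mol), after
#: Benham (1992) and Bi & Benham (2004).
DEFAULT_SIDD_PARAMS = {
    "a_kcal": 10.84,          # initiation cost per open run
    "b_AT_kcal": 0.26,        # separation energy per A:T bp
    "b_GC_kcal": 1.30,        # separation energy per G:C bp
    "c_open_kcal_per_rad2": 3.6,   # torsional stiffness of open strands
    "K_coeff": 2200.0,        # residual-stress coefficient: K=coeff*RT/N
    "helical_repeat": 10.4,
}


def _sidd_energy_terms(n_bp: int, sigma: float, temperature_K: float,
                       params: dict):
    """Residual-superhelicity energy Es(n) for n open bp, after
    analytic minimisation over the interstrand winding of the open
    region, plus per-bp separation energies."""
    RT = R_KCAL * temperature_K
    h = params["helical_repeat"]
    K = params["K_coeff"] * RT / n_bp
    C = params["c_open_kcal_per_rad2"]
    alpha = sigma * n_bp / h
    n = np.arange(n_bp + 1, dtype=float)
    # min over tau of C/2*n*tau^2 + K/2*(alpha + n/h - n*tau/2pi)^2
    keff = np.where(n > 0, K * C / (C + K * n / (4 * math.pi ** 2)), K)
    Es = 0.5 * keff * (alpha + n / h) ** 2
    return Es, alpha, RT


def sidd_profile(seq, sigma: float, salt_M: float = 0.1,
                 temperature_K: float = 310.0, max_runs: int = 2,
                 energy_ceiling_kcal: float = 12.0,
                 params: dict | None = None,
                 max_candidate_runs: int = 5000) -> OpeningProfile:
    """Equilibrium per-bp opening probability under superhelical
    stress.

    States are the closed duplex plus configurations of at most
    `max_runs` disjoint contiguous open runs.  A state's energy is the
    initiation cost per run, the per-bp separation energies, and the
    residual-superhelicity quadratic term after analytic minimisation
    over the winding of the open strands.  All states within
    `energy_ceiling_kcal` of the minimum are Boltzmann-summed.

    The quoted separation energies are calibrated near 0.1 M salt and
    310 K; `salt_M` is recorded with the profile, and other ionic
    conditions should be expressed by overriding `params`.  For
    sigma >= 0 there is no driving stress and the profile is
    essentially zero (a note is attached).
    """
    s = _seq_str(seq)
    n_bp = len(s)
    if n_bp < 50:
        raise ValueError("sequence too short for a profile (>= 50 bp)")
    if n_bp > 20000:
        raise ValueError("sequence above the ~20 kbp desk scale; split it "
                         "or use a genomic-scale implementation")
    p = dict(DEFAULT_SIDD_PARAMS)
    if params:
        p.update(params)
    Es, alpha, RT = _sidd_energy_terms(n_bp, sigma, temperature_K, p)
    b = np.where(np.isin(list(s), ["A", "T"]), p["b_AT_kcal"],
                 p["b_GC_kcal"])
    pre = np.concatenate([[0.0], np.cumsum(b)])
    a = p["a_kcal"]

    E_closed = Es[0]
    ceiling = energy_ceiling_kcal

    # pass 1: provisional minimum over closed + single-run states, and
    # the largest run length worth enumerating
    E_min = E_closed
    L_max = 0
    miss = 0
    for L in range(1, n_bp + 1):
        B = pre[L:] - pre[:-L]
        e_min_L = a + B.min() + Es[L]
        if e_min_L < E_min:
            E_min = e_min_L
        if e_min_L > E_min + ceiling:
            miss += 1
            if miss > 30:
                break
        else:
            miss = 0
            L_max = L
    L_max = max(L_max, 1)

    diff = np.zeros(n_bp + 1)
    Z = math.exp(-(E_closed - E_min) / RT)
    run_len_w: dict[int, float] = {}
    # pass 2: single runs
    for L in range(1, L_max + 1):
        B = pre[L:] - pre[:-L]
        E = a + B + Es[L]
        m = E <= E_min + ceiling
        if not m.any():
            continue
        w = np.exp(-(E[m] - E_min) / RT)
        starts = np.flatnonzero(m)
        np.add.at(diff, starts, w)
        np.add.at(diff, starts + L, -w)
        Z += w.sum()
        run_len_w[L] = run_len_w.get(L, 0.0) + float(w.sum())

    # pass 3: two-run states, from pruned candidate runs
    if max_runs >= 2:
        Es_min = float(Es[2:].min()) if n_bp >= 2 else 0.0
        partner_floor = a + b.min() + 0.0
        cands = []          # (g = a + B, start, L)
        for L in range(1, L_max + 1):
            B = pre[L:] - pre[:-L]
            g = a + B
            m = g + partner_floor + Es_min <= E_min + ceiling
            for st in np.flatnonzero(m):
                cands.append((float(g[st]), int(st), L))
        cands.sort()
        cands = cands[:max_candidate_runs]
        for i in range(len(cands)):
            g1, s1, L1 = cands[i]
            for j in range(i + 1, len(cands)):
                g2, s2, L2 = cands[j]
                if g1 + g2 + Es_min > E_min + ceiling:
                    continue
                # disjoint with >= 1 closed bp between runs
                if s1 <= s2:
                    if s2 <= s1 + L1:
                        continue
                else:
                    if s1 <= s2 + L2:
                        continue
                E = g1 + g2 + Es[L1 + L2]
                if E > E_min + ceiling:
                    continue
                w = math.exp(-(E - E_min) / RT)
                diff[s1] += w
                diff[s1 + L1] -= w
                diff[s2] += w
                diff[s2 + L2] -= w
                Z += w
                run_len_w[L1] = run_len_w.get(L1, 0.0) + w
                run_len_w[L2] = run_len_w.get(L2, 0.0) + w

    prob = np.cumsum(diff[:-1]) / Z
    prob = np.clip(prob, 0.0, 1.0)
    note = ""
    if sigma >= 0:
        note = ("sigma >= 0: no destabilising stress, profile is "
                "essentially zero")
    return OpeningProfile(probabilities=prob, sigma=sigma, salt_M=salt_M,
                          temperature_K=temperature_K, params=p,
                          run_length_weights=run_len_w, note=note)


def expected_bubble_size(profile: OpeningProfile) -> float:
    """Probability-weighted mean open-run length (nt) of a profile."""
    if not profile.run_length_weights:
        raise ValueError("profile carries no open states; expected bubble "
                         "size undefined")
    total = sum(profile.run_length_weights.values())
    if total <= 0:
        raise ValueError("all-zero opening profile")
    return sum(L * w for L, w in profile.run_length_weights.items()) / total


def write_bedgraph(values, path, chrom: str = "seq") -> None:
    """Export a per-bp profile as bedGraph (0-based half-open
    intervals, adjacent equal values merged)."""
    y = np.asarray(values, float)
    lines = []
    start = 0
    for i in range(1, y.size + 1):
        if i == y.size or y[i] != y[start]:
            lines.append(f"{chrom}\t{start}\t{i}\t{y[start]:.6g}")
            start = i
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def _peak_positions(y: np.ndarray, prominence_frac: float = 0.05):
    y = np.asarray(y, float)
    if y.max() <= y.min():
        return np.array([], dtype=int)
    yn = (y - y.min()) / (y.max() - y.min())
    pk, _ = signal.find_peaks(yn, prominence=prominence_frac)
    return pk


def compare_profiles(profile_a, profile_b, smooth_b: bool = False,
                     prominence_frac: float = 0.05) -> dict:
    """Match peaks between two per-bp profiles (prediction vs
    prediction, or prediction vs a measured intensity trace).

    Inputs may be OpeningProfile / PlectonemeProfile or raw arrays on
    the same bp coordinates; both are min-max normalised before peak
    finding, so the matching is invariant to uniform intensity
    scaling.  With `smooth_b` the second profile (e.g. a measured
    fluorescence line profile) is cubic-spline smoothed first.  Offsets
    are reported as a percentage of the sequence length.
    """
    def as_arr(prof):
        if isinstance(prof, OpeningProfile):
            return prof.probabilities
        if isinstance(prof, PlectonemeProfile):
            return prof.density
        return np.asarray(prof, float)

    a = as_arr(profile_a)
    bb = as_arr(profile_b)
    if a.size != bb.size:
        raise ValueError("profiles must share bp coordinates")
    if smooth_b:
        x = np.arange(bb.size)
        spl = interpolate.UnivariateSpline(x, bb, k=3,
                                           s=bb.size * np.var(bb) * 0.01)
        bb = spl(x)
    pa = _peak_positions(a, prominence_frac)
    pb = _peak_positions(bb, prominence_frac)
    if pa.size == 0 or pb.size == 0:
        return {"matches": [], "n_peaks_a": int(pa.size),
                "n_peaks_b": int(pb.size)}
    matches = []
    for x0 in pa:
        j = int(np.argmin(np.abs(pb - x0)))
        matches.append({"peak_a_bp": int(x0) + 1,
                        "peak_b_bp": int(pb[j]) + 1,
                        "offset_bp": int(pb[j] - x0),
                        "offset_percent":
                            100.0 * abs(int(pb[j]) - int(x0)) / a.size})
    return {"matches": matches, "n_peaks_a": int(pa.size),
            "n_peaks_b": int(pb.size)}
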
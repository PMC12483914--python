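"""Evolutionary and biochemical window encodings.

The evolutionary stream of the predictor is a position-specific scoring
matrix (PSSM): per-position log-odds of amino-acid substitution produced by
iterative profile alignment (PSI-BLAST, three iterations, E = 0.001, against
NR — that invocation is the provenance recipe, not something this package
runs).  This module parses the standard PSI-BLAST ASCII profile layout,
slices ±10-residue windows out of a profile (zero rows for the X pads), and
optionally squashes scores through the logistic 1/(1+e^{−x}) so the network
sees bounded inputs.

Baseline encoders — BLOSUM62 rows, amino-acid composition (AAC) and one-hot —
and a seed-deterministic synthetic profile generator (stand-in for real
PSI-BLAST output on synthetic windows) complete the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .seqdata import AMINO_ACIDS, PeptideWindow, WINDOW_LENGTH

#: Canonical amino-acid column order used everywhere (PSI-BLAST header order).
CANONICAL_ORDER = "ARNDCQEGHILKMFPSTWYV"
_CANON_INDEX = {a: i for i, a in enumerate(CANONICAL_ORDER)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class PSSMParseError(ValueError):
    pass


@dataclass
class PSSMProfile:
    """Per-position substitution log-odds for one protein.

    ``scores`` is L × 20 (row = sequence position, column = amino acid in
    :data:`CANONICAL_ORDER`); ``residues`` is the protein sequence of length L.
    """

    protein_id: str
    scores: np.ndarray
    residues: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.residues), 20):
            raise ValueError("scores must be len(residues) x 20")


def parse_pssm(text: str, protein_id: str = "",
               use_percentages: bool = False) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM.

    By default the first 20 numeric columns per row (the log-odds block) are
    used and the weighted-percentage block plus trailing statistics are
    ignored; ``use_percentages`` switches to columns 21–40 instead.  The
    amino-acid column order is taken from the file's own header and remapped
    to :data:`CANONICAL_ORDER`.
    """
    lines = text.splitlines()
    header_order: list[str] | None = None
    header_line = -1
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t in AMINO_ACIDS for t in toks[:20]):
            header_order = toks[:20]
            header_line = i
            break
    if header_order is None:
        raise PSSMParseError("no amino-acid column header found")
    if len(set(header_order)) != 20:
        raise PSSMParseError(f"line {header_line + 1}: header does not list 20 distinct amino acids")

    remap = [header_order.index(a) for a in CANONICAL_ORDER]
    rows, residues = [], []
    expected_pos = 1
    for lineno in range(header_line + 1, len(lines)):
        toks = lines[lineno].split()
        if not toks:
            continue
        if not toks[0].isdigit():
            break  # footer (Lambda/K statistics)
        if len(toks) < 2 or len(toks[1]) != 1:
            raise PSSMParseError(f"line {lineno + 1}: expected 'index residue scores...'")
        nums = toks[2:]
        lo, hi = (20, 40) if use_percentages else (0, 20)
        if len(nums) < hi:
            raise PSSMParseError(
                f"line {lineno + 1}: expected >={hi} numeric columns, got {len(nums)}")
        try:
            vals = [float(v) for v in nums[lo:hi]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno + 1}: non-numeric cell: {exc}") from exc
        if int(toks[0]) != expected_pos:
            raise PSSMParseError(f"line {lineno + 1}: position index out of order")
        expected_pos += 1
        rows.append([vals[j] for j in remap])
        residues.append(toks[1].upper())
    if not rows:
        raise PSSMParseError("no per-position rows found")
    return PSSMProfile(protein_id, np.array(rows), "".join(residues))


def serialize_pssm(profile: PSSMProfile) -> str:
    """Write a profile back into the ASCII layout accepted by :func:`parse_pssm`."""
    out = ["Last position-specific scoring matrix computed", ""]
    out.append("            " + "   ".join(CANONICAL_ORDER))
    for i, (res, row) in enumerate(zip(profile.residues, profile.scores), 1):
        cells = " ".join(f"{v:4.0f}" if float(v).is_integer() else f"{v:7.3f}"
                         for v in row)
        out.append(f"{i:5d} {res}  {cells}")
    return "\n".join(out) + "\n"


def window_pssm_features(profile: PSSMProfile, center: int, radius: int = 10,
                         squash: bool = True) -> np.ndarray:
    """Slice the profile rows at center ± radius (1-based center) → 21 × 20.

    Positions outside the protein (the window's X pads) become all-zero rows.
    With ``squash``, in-protein scores pass through the logistic function.
    """
    L = len(profile.residues)
    if center < 1 or center > L:
        raise IndexError(f"center {center} outside profile of length {L}")
    out = np.zeros((2 * radius + 1, 20))
    for i, off in enumerate(range(-radius, radius + 1)):
        j = center - 1 + off
        if 0 <= j < L:
            row = profile.scores[j]
            out[i] = 1.0 / (1.0 + np.exp(-row)) if squash else row
    return out


def synthetic_pssm(window: PeptideWindow | str, seed: int = 0,
                   protein_id: str = "synthetic") -> PSSMProfile:
    """A 21-position profile fragment consistent with the window's residues.

    Synthetic stand-in for PSI-BLAST output: at each non-X position the
    observed residue's column draws a high integer score (5–9) and all other
    columns small integer noise (−3…2); X positions are all zero.  Marked
    synthetic by its default protein_id.
    """
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    rng = np.random.default_rng(seed)
    scores = np.zeros((len(seq), 20))
    for i, res in enumerate(seq):
        if res == "X":
            continue
        row = rng.integers(-3, 3, size=20).astype(np.float64)  # noise in -3..2
        row[_CANON_INDEX[res]] = rng.integers(5, 10)
        scores[i] = row
    return PSSMProfile(protein_id, scores, seq)


# ---------------------------------------------------------------------------
# baseline encoders
# ---------------------------------------------------------------------------

def encode_blosum62(window: PeptideWindow | str) -> np.ndarray:
    """Per-residue BLOSUM62 substitution rows → 21 × 20 ('X' rows are zero)."""
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    out = np.zeros((len(seq), 20))
    for i, res in enumerate(seq):
        if res == "X":
            continue
        out[i] = [_BLOSUM62[res][b] for b in CANONICAL_ORDER]
    return out


def encode_aac(window: PeptideWindow | str) -> np.ndarray:
    """Amino-acid composition over non-X positions → length-20 frequency vector."""
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    counts = np.zeros(20)
    for res in seq:
        if res != "X":
            counts[_CANON_INDEX[res]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def encode_onehot(window: PeptideWindow | str) -> np.ndarray:
    """Indicator encoding over the 21-symbol alphabet → 21 × 21."""
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    idx = {c: i for i, c in enumerate(CANONICAL_ORDER + "X")}
    out = np.zeros((len(seq), 21))
    for i, res in enumerate(seq):
        out[i, idx[res]] = 1.0
    return out


def encode_windows_pssm(windows: list[PeptideWindow],
                        profiles: dict[str, PSSMProfile] | None = None,
                        squash: bool = True, seed: int = 0) -> np.ndarray:
    """Evolutionary features for a window list → (n, 21, 20).

    Real profiles are used when supplied (keyed by protein_id, sliced at each
    window's center); otherwise a per-window synthetic profile is generated,
    seeded per window index for determinism.
    """
    feats = np.zeros((len(windows), WINDOW_LENGTH, 20))
    for i, w in enumerate(windows):
        if profiles is not None and w.protein_id in profiles:
            feats[i] = window_pssm_features(profiles[w.protein_id],
                                            w.center_position, squash=squash)
        else:
            frag = synthetic_pssm(w, seed=seed + i)
            fi = window_pssm_features(frag, WINDOW_LENGTH // 2 + 1, squash=squash)
            # X pads sit inside the synthetic fragment; keep them zero features
            for j, res in enumerate(w.sequence):
                if res == "X":
                    fi[j] = 0.0
            feats[i] = fi
    return feats
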
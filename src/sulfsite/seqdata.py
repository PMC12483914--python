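"""Peptide-window construction and synthetic datasets for sulfenylation sites.

Candidate S-sulfenylation sites are represented as 21-residue windows centered
on a cysteine: ten residues upstream, the cysteine, ten downstream.  Where the
protein ends inside the window, the placeholder residue ``X`` pads the flank.
Windows sharing more than a similarity threshold (default 40%, measured as the
fraction of identical aligned positions over the gapless 21-mer) are removed
by a greedy first-seen-kept scan to curb homology bias.

The module also provides a synthetic-data generator that emits labelled
windows with planted position-specific residue enrichment (emulating the
lysine/glutamate bias observed around redox-reactive cysteines) together with
plain-text FASTA / TSV / CSV I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes
ALPHABET = AMINO_ACIDS + "X"
WINDOW_LENGTH = 21
CENTER_INDEX = 10  # 0-based center of a 21-residue window

#: Approximate background amino-acid frequencies in vertebrate proteomes
#: (UniProt/Swiss-Prot composition statistics, rounded), normalised to 1.
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_total = sum(BACKGROUND_FREQS.values())
BACKGROUND_FREQS = {a: v / _total for a, v in BACKGROUND_FREQS.items()}

# Ambiguity / non-standard codes folded into the placeholder residue.
_NONSTANDARD = set("BZUOJ*")


class SiteValidationError(ValueError):
    """An annotation does not point at a cysteine or lies off the protein."""


@dataclass(frozen=True)
class PeptideWindow:
    """A 21-residue window centered on a candidate cysteine."""

    sequence: str
    label: int
    protein_id: str = ""
    center_position: int = 0  # 1-based position in the source protein

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have {WINDOW_LENGTH} residues, got {len(self.sequence)}"
            )
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid residues in window: {sorted(bad)}")


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    position: int  # 1-based
    label: int


@dataclass
class SyntheticConfig:
    """Conditions for the planted-signal window generator.

    ``enrichment_table`` maps ``(relative_position, residue)`` — positions in
    −10…10 with 0 the central cysteine — to an additive probability boost for
    that residue at that position in *positive* windows.  The boosted residue
    receives ``background + boost`` and the remaining residues are rescaled to
    keep the distribution normalised.
    """

    n_positive: int = 2000
    n_negative: int = 4000
    enrichment_table: dict[tuple[int, str], float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    seed: int = 0

    def __post_init__(self):
        if self.n_positive <= 0 or self.n_negative <= 0:
            raise ValueError("sample counts must be positive")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")


def planted_ke_enrichment(boost: float = 0.15,
                          positions: tuple[int, ...] = (-3, -2, -1, 1, 2, 3),
                          residues: str = "KE") -> dict[tuple[int, str], float]:
    """Default planted signal: Lys/Glu excess flanking the central cysteine.

    Emulates the enrichment of charged residues near redox-modified cysteines;
    the default boosts K and E by +0.15 each at positions ±1..±3.
    """
    return {(p, r): boost for p in positions for r in residues}


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def extract_windows(protein_sequence: str,
                    annotations: list[SiteAnnotation],
                    radius: int = 10) -> list[PeptideWindow]:
    """Cut one X-padded window of width ``2*radius + 1`` per annotation.

    Annotated positions are 1-based and must index a cysteine.
    """
    seq = normalize_sequence(protein_sequence)
    n = len(seq)
    windows = []
    for ann in annotations:
        if ann.position < 1 or ann.position > n:
            raise SiteValidationError(
                f"{ann.protein_id}: position {ann.position} outside protein of length {n}"
            )
        if seq[ann.position - 1] != "C":
            raise SiteValidationError(
                f"{ann.protein_id}: residue at position {ann.position} is "
                f"'{seq[ann.position - 1]}', expected 'C'"
            )
        chars = []
        for off in range(-radius, radius + 1):
            j = ann.position - 1 + off
            chars.append(seq[j] if 0 <= j < n else "X")
        windows.append(PeptideWindow("".join(chars), int(ann.label),
                                     ann.protein_id, ann.position))
    return windows


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map non-standard residue codes (B, Z, U, O, …) to X."""
    seq = sequence.upper()
    if any(c in _NONSTANDARD for c in seq):
        logger.warning("non-standard residues mapped to X in sequence")
        seq = "".join("X" if c in _NONSTANDARD else c for c in seq)
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"unknown residue codes: {sorted(bad)}")
    return seq


def window_similarity(a: str, b: str) -> float:
    """Fraction of identical aligned positions (X–X counts as identical)."""
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def redundancy_filter(windows: list[PeptideWindow],
                      threshold: float = 0.40) -> list[PeptideWindow]:
    """Greedy first-seen-kept deduplication at a similarity threshold.

    A window is dropped iff its position-wise identity fraction with any
    already-retained window strictly exceeds ``threshold``.
    """
    if not windows:
        return []
    length = len(windows[0].sequence)
    cutoff = threshold * length  # drop when identical positions > cutoff
    kept: list[PeptideWindow] = []
    kept_mat = np.empty((0, length), dtype=np.uint8)
    for w in windows:
        row = np.frombuffer(w.sequence.encode("ascii"), dtype=np.uint8)
        if kept_mat.shape[0]:
            matches = (kept_mat == row).sum(axis=1)
            if (matches > cutoff).any():
                continue
        kept.append(w)
        kept_mat = np.vstack([kept_mat, row[None, :]])
    return kept


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

def _position_distribution(background: dict[str, float],
                           boosts: dict[str, float]) -> np.ndarray:
    """Per-position residue distribution with additive boosts applied."""
    aas = list(AMINO_ACIDS)
    base = np.array([background[a] for a in aas])
    if not boosts:
        return base
    probs = base.copy()
    boosted_idx = []
    for res, boost in boosts.items():
        i = aas.index(res)
        probs[i] = base[i] + boost
        boosted_idx.append(i)
    if (probs < 0).any() or probs[boosted_idx].sum() > 1.0:
        raise ValueError("enrichment boosts produce an invalid probability distribution")
    rest = [i for i in range(len(aas)) if i not in boosted_idx]
    remaining = 1.0 - probs[boosted_idx].sum()
    probs[rest] = base[rest] * (remaining / base[rest].sum())
    return probs


def generate_synthetic_dataset(config: SyntheticConfig
                               ) -> tuple[list[PeptideWindow], list[int]]:
    """Draw labelled windows: positives with planted enrichment, negatives i.i.d.

    Every window has 'C' at the center.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    aas = np.array(list(AMINO_ACIDS))
    radius = CENTER_INDEX

    # per-position distributions for the positive class
    pos_dists = []
    for off in range(-radius, radius + 1):
        boosts = {res: b for (p, res), b in config.enrichment_table.items() if p == off}
        pos_dists.append(_position_distribution(config.background, boosts))
    neg_dist = _position_distribution(config.background, {})

    windows: list[PeptideWindow] = []
    labels: list[int] = []
    for label, count, dists in (
        (1, config.n_positive, pos_dists),
        (0, config.n_negative, [neg_dist] * WINDOW_LENGTH),
    ):
        cols = []
        for i, dist in enumerate(dists):
            if i == CENTER_INDEX:
                cols.append(np.full(count, "C"))
            else:
                cols.append(rng.choice(aas, size=count, p=dist))
        mat = np.stack(cols, axis=1)
        for k in range(count):
            windows.append(PeptideWindow("".join(mat[k]), label,
                                         protein_id=f"synth_{label}_{k}",
                                         center_position=CENTER_INDEX + 1))
            labels.append(label)
    return windows, labels


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}.

    The record id is the first whitespace-delimited token of the header.
    """
    proteins: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    proteins[current] = "".join(chunks)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                current = header.split()[0]
                chunks = []
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
                chunks.append(line.strip().upper())
    if current is not None:
        proteins[current] = "".join(chunks)
    return proteins


def read_sites(path) -> list[SiteAnnotation]:
    """Read a TSV of site annotations: protein_id <tab> position <tab> label."""
    sites = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "protein_id":
                continue
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, pos_s, label_s = parts
            try:
                pos = int(pos_s)
                label = int(label_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if label not in (0, 1):
                raise ParseError(f"{path}:{lineno}: label must be 0 or 1")
            sites.append(SiteAnnotation(pid, pos, label))
    return sites


def write_dataset(windows: list[PeptideWindow], labels: list[int], path) -> None:
    """Write windows as CSV with columns protein_id,center_position,sequence,label."""
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id,center_position,sequence,label\n")
        for w, y in zip(windows, labels):
            fh.write(f"{w.protein_id},{w.center_position},{w.sequence},{int(y)}\n")


def read_dataset(path) -> tuple[list[PeptideWindow], list[int]]:
    """Read a CSV written by :func:`write_dataset`."""
    windows, labels = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "protein_id,center_position,sequence,label":
            raise ParseError(f"{path}:1: unexpected CSV header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            pid, pos_s, seq, label_s = parts
            windows.append(PeptideWindow(seq, int(label_s), pid, int(pos_s)))
            labels.append(int(label_s))
    return windows, labels
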
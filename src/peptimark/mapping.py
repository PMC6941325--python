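"""In-silico protease mapping of peptide terminal motifs.

Endogenous peptides are proteolysis products: the eight residues flanking each
cut site (P4-P3-P2-P1 | P1'-P2'-P3'-P4') carry the signature of the protease
that made the cut. Each candidate protease is described by a specificity
weight matrix — one probability distribution over the 20 residues per motif
position. A marker peptide with known parent-protein coordinates yields two
octapeptide motifs (around its N- and its C-terminal cut); each motif is
scored against each matrix by additive log2 odds versus a background residue
distribution, and an assignment is called when the score reaches the matrix's
threshold (by default the 95th percentile of the matrix's score distribution
on random octapeptides).

Because any scoring threshold admits chance hits, the same matrices are also
applied to random decoy octapeptides. Scaling the decoy hit count to the
number of target motifs gives an expected false-positive count and hence a
positive predictive value PPV = TP / (TP + FP) per protease; proteases are
retained when PPV > 0.65 and they are supported by at least four distinct
cleavage sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .profiles import PeptideRecord

__all__ = [
    "RESIDUES",
    "MOTIF_POSITIONS",
    "SpecificityMatrix",
    "CleavageMotif",
    "ProteaseAssignment",
    "PPVReport",
    "extract_terminal_motifs",
    "score_motif",
    "generate_decoys",
    "calibrate_threshold",
    "map_proteases",
    "compute_ppv",
    "read_matrices_json",
    "write_matrices_json",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RES_INDEX = {r: i for i, r in enumerate(RESIDUES)}
MOTIF_POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")
UNIFORM_BACKGROUND = np.full(20, 1 / 20)


@dataclass
class SpecificityMatrix:
    """Per-protease P4-P4' specificity weight matrix.

    ``weights`` has shape (8 positions, 20 residues); each position row is a
    probability distribution over residues (ordered as :data:`RESIDUES`).
    ``score_threshold`` is the minimum motif score for a predicted cleavage.
    """

    protease_id: str
    weights: np.ndarray
    score_threshold: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.shape != (8, 20):
            raise ValidationError(
                f"weights must be 8 positions x 20 residues, got {self.weights.shape}"
            )
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("each position's weights must sum to 1")
        if not np.isfinite(self.score_threshold):
            raise ValidationError("score_threshold must be finite")

    @property
    def log_odds(self) -> np.ndarray:
        """8x20 matrix of log2(weight / background), floored at -60 bits."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.weights / self.background)
        return np.maximum(lo, -60.0)


@dataclass(frozen=True)
class CleavageMotif:
    """Octapeptide motif around one terminus of a marker peptide.

    ``residues`` is an 8-character string over the 20 residues plus ``X`` for
    positions falling outside the parent sequence. ``position`` is the cut
    site: cleavage occurs after parent residue ``position`` (1-based), i.e.
    between P1 and P1'.
    """

    marker_id: str
    terminus: str  # "N" or "C"
    residues: str
    parent_id: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValidationError(f"motif must have 8 residues, got {self.residues!r}")
        if self.terminus not in ("N", "C"):
            raise ValidationError("terminus must be 'N' or 'C'")
        bad = set(self.residues) - set(RESIDUES) - {"X"}
        if bad:
            raise ValidationError(f"unknown residues in motif: {sorted(bad)}")

    @property
    def site(self) -> tuple[str | None, int | None]:
        return (self.parent_id, self.position)


@dataclass(frozen=True)
class ProteaseAssignment:
    """One (motif, protease) hit at or above the matrix threshold."""

    protease_id: str
    marker_id: str
    terminus: str
    score: float
    parent_id: str | None = None
    position: int | None = None

    @property
    def site(self) -> tuple:
        if self.parent_id is None and self.position is None:
            # unplaced motif (e.g. a decoy): its identity is the site
            return (self.marker_id, self.terminus)
        return (self.parent_id, self.position)


@dataclass(frozen=True)
class PPVReport:
    """Decoy-calibrated positive-predictive-value summary for one protease."""

    protease_id: str
    target_hits: int
    decoy_hits_scaled: float
    ppv: float
    n_sites: int
    retained: bool


def extract_terminal_motifs(
    marker: PeptideRecord,
    parent_sequence: str,
    marker_id: str = "",
) -> tuple[CleavageMotif, CleavageMotif]:
    """Extract the N- and C-terminal cleavage motifs of a sequenced marker.

    For a peptide spanning parent positions ``start..end`` (1-based,
    inclusive), the N-terminal cut lies after parent residue ``start - 1`` and
    its motif covers parent positions ``start-4 .. start+3``; the C-terminal
    cut lies after residue ``end`` with motif ``end-3 .. end+4``. Positions
    outside the parent are padded with ``X`` (a peptide at the protein
    terminus has no flanking residues there).
    """
    if marker.parent_id is None or marker.start is None or marker.end is None:
        raise ValidationError("marker must carry parent_id, start and end")
    n = len(parent_sequence)
    if not (1 <= marker.start <= marker.end <= n):
        raise ValidationError(
            f"coordinates {marker.start}-{marker.end} outside parent of length {n}"
        )

    def window(first: int) -> str:  # first = 1-based position of the P4 residue
        out = []
        for pos in range(first, first + 8):
            out.append(parent_sequence[pos - 1] if 1 <= pos <= n else "X")
        return "".join(out)

    n_motif = CleavageMotif(marker_id, "N", window(marker.start - 4),
                            marker.parent_id, marker.start - 1)
    c_motif = CleavageMotif(marker_id, "C", window(marker.end - 3),
                            marker.parent_id, marker.end)
    return n_motif, c_motif


def encode_motifs(motifs: Sequence[str]) -> np.ndarray:
    """Encode motif strings as an int array; X -> 20 (scores as zero)."""
    table = np.full(128, -1, dtype=np.int8)
    for r, i in _RES_INDEX.items():
        table[ord(r)] = i
    table[ord("X")] = 20
    arr = np.frombuffer("".join(motifs).encode(), dtype=np.uint8).reshape(len(motifs), 8)
    codes = table[arr]
    if (codes < 0).any():
        raise ValidationError("motif contains unknown residue")
    return codes.astype(np.intp)


def score_motifs(matrix: SpecificityMatrix, codes: np.ndarray) -> np.ndarray:
    """Vectorized motif scoring (bits); ``codes`` from :func:`encode_motifs`."""
    lo = np.vstack([matrix.log_odds.T, np.zeros((1, 8))])  # 21st row: X -> 0
    return lo[codes, np.arange(8)].sum(axis=1)


def score_motif(matrix: SpecificityMatrix, motif: CleavageMotif | str) -> float:
    """Score one motif: sum over positions of log2(weight / background).

    ``X`` positions contribute zero, keeping markers at protein termini
    mappable.
    """
    residues = motif.residues if isinstance(motif, CleavageMotif) else motif
    if len(residues) != 8:
        raise ValidationError("motif length must be 8")
    return float(score_motifs(matrix, encode_motifs([residues]))[0])


def generate_decoys(
    n: int,
    seed: int | np.random.Generator,
    frequencies: np.ndarray | None = None,
) -> list[str]:
    """Draw ``n`` random octapeptides i.i.d. from the background frequencies."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = UNIFORM_BACKGROUND if frequencies is None else np.asarray(frequencies, float)
    chars = np.array(list(RESIDUES))
    draws = rng.choice(20, size=(n, 8), p=freqs / freqs.sum())
    return ["".join(row) for row in chars[draws]]


def calibrate_threshold(
    matrix: SpecificityMatrix,
    decoys: Sequence[str],
    percentile: float = 95.0,
) -> float:
    """Score threshold = the given percentile of the decoy score distribution."""
    scores = score_motifs(matrix, encode_motifs(list(decoys)))
    return float(np.percentile(scores, percentile))


def map_proteases(
    motifs: Sequence[CleavageMotif],
    matrices: Sequence[SpecificityMatrix],
) -> list[ProteaseAssignment]:
    """Assign motifs to proteases: every (motif, matrix) pair scoring at or
    above the matrix's ``score_threshold`` yields an assignment. A motif may
    map to several proteases.
    """
    if not motifs:
        raise ValidationError("no motifs to map")
    codes = encode_motifs([m.residues for m in motifs])
    out: list[ProteaseAssignment] = []
    for matrix in matrices:
        scores = score_motifs(matrix, codes)
        for i in np.flatnonzero(scores >= matrix.score_threshold):
            m = motifs[i]
            out.append(ProteaseAssignment(
                matrix.protease_id, m.marker_id, m.terminus,
                float(scores[i]), m.parent_id, m.position,
            ))
    return out


def compute_ppv(
    target_assignments: Iterable[ProteaseAssignment],
    decoy_assignments: Iterable[ProteaseAssignment],
    n_targets: int,
    n_decoys: int,
    ppv_cutoff: float = 0.65,
    min_sites: int = 4,
) -> list[PPVReport]:
    """Decoy-calibrated PPV filter.

    Per protease, the decoy hit count is scaled by ``n_targets / n_decoys``
    to an expected false-positive count FP; PPV = TP / (TP + FP) where TP is
    the target motif hit count. A protease is retained iff PPV strictly
    exceeds ``ppv_cutoff`` and its target hits cover at least ``min_sites``
    distinct cleavage sites. Proteases with no hits in either set are
    omitted.
    """
    if n_decoys < n_targets:
        raise ValidationError("need n_decoys >= n_targets for stable FP scaling")
    if n_targets < 1:
        raise ValidationError("n_targets must be >= 1")
    tp: dict[str, list[ProteaseAssignment]] = {}
    dec: dict[str, int] = {}
    for a in target_assignments:
        tp.setdefault(a.protease_id, []).append(a)
    for a in decoy_assignments:
        dec[a.protease_id] = dec.get(a.protease_id, 0) + 1
    reports = []
    for pid in sorted(set(tp) | set(dec)):
        hits = tp.get(pid, [])
        fp = dec.get(pid, 0) * (n_targets / n_decoys)
        n_tp = len(hits)
        if n_tp + fp == 0:
            continue
        ppv = n_tp / (n_tp + fp)
        n_sites = len({a.site for a in hits})
        reports.append(PPVReport(
            protease_id=pid, target_hits=n_tp, decoy_hits_scaled=fp,
            ppv=ppv, n_sites=n_sites,
            retained=(ppv > ppv_cutoff and n_sites >= min_sites),
        ))
    return reports


# ---------------------------------------------------------------------------
# JSON I/O for matrices


def write_matrices_json(matrices: Sequence[SpecificityMatrix], path: str | Path) -> None:
    payload = [
        {
            "protease_id": m.protease_id,
            "positions": list(MOTIF_POSITIONS),
            "residues": RESIDUES,
            "weights": m.weights.tolist(),
            "threshold": m.score_threshold,
            "background": m.background.tolist(),
        }
        for m in matrices
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_matrices_json(path: str | Path) -> list[SpecificityMatrix]:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        out.append(SpecificityMatrix(
            protease_id=entry["protease_id"],
            weights=np.array(entry["weights"], dtype=float),
            score_threshold=float(entry.get("threshold", 0.0)),
            background=np.array(entry.get("background", UNIFORM_BACKGROUND), dtype=float),
        ))
    return out
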
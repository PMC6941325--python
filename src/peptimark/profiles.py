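"""CE-MS peptide profiles: data model, I/O, normalization and cross-sample matching.

A CE-MS (capillary electrophoresis coupled to mass spectrometry) run reduces a
body-fluid sample to a list of peptides, each characterized by its monoisotopic
mass (Da), its normalized CE migration time (min) and its ion signal intensity.
This module holds the in-memory model for such profiles, reads and writes the
plain-TSV dialect used throughout the package, performs internal-standard
normalization of ion signals, and matches peptides across samples of a cohort
into a peptide x sample intensity matrix ("profile matrix") on which all
downstream statistics operate.

Matching uses mass-dependent ppm tolerances (small peptides are matched more
tightly than large ones) and a migration-time tolerance that widens linearly
with migration time, reflecting analyte diffusion (CE peaks broaden late in
the run).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError, ValidationError

__all__ = [
    "PeptideRecord",
    "SampleProfile",
    "MatchingParams",
    "ProfileMatrix",
    "read_profiles",
    "write_profiles",
    "normalize_profile",
    "mass_tolerance",
    "migration_tolerance",
    "match_peptides",
    "read_matrix",
    "write_matrix",
]

FLUIDS = ("bile", "urine")
GROUPS = ("CCA", "PSC", "BBD", "CCA_on_PSC")

#: TSV columns; the last four are optional (sequenced peptides only).
PROFILE_COLUMNS = ("sample_id", "fluid", "group", "mass", "cetime", "intensity")
OPTIONAL_COLUMNS = ("sequence", "parent_id", "start", "end")


@dataclass(frozen=True)
class PeptideRecord:
    """One detected peptide.

    Parameters
    ----------
    mass : float
        Monoisotopic mass in Da, > 0.
    cetime : float
        Normalized CE migration time in minutes, > 0.
    intensity : float
        Normalized ion signal (arbitrary counts), >= 0.
    sequence, parent_id, start, end : optional
        Amino-acid sequence and 1-based inclusive coordinates in the parent
        protein, when the peptide has been sequenced.
    """

    mass: float
    cetime: float
    intensity: float
    sequence: str | None = None
    parent_id: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"mass must be > 0, got {self.mass}")
        if not self.cetime > 0:
            raise ValidationError(f"cetime must be > 0, got {self.cetime}")
        if not self.intensity >= 0:
            raise ValidationError(f"intensity must be >= 0, got {self.intensity}")
        if self.sequence is not None and self.start is not None and self.end is not None:
            if self.end - self.start + 1 != len(self.sequence):
                raise ValidationError(
                    f"coordinates {self.start}-{self.end} inconsistent with "
                    f"sequence length {len(self.sequence)}"
                )


@dataclass
class SampleProfile:
    """All peptides detected in one patient-fluid sample."""

    sample_id: str
    fluid: str
    group: str
    peptides: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValidationError(f"fluid must be one of {FLUIDS}, got {self.fluid!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.peptides:
            raise ValidationError(
                f"non-empty profile required for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class MatchingParams:
    """Cross-sample matching tolerances.

    ``ppm_small``/``ppm_large`` are the mass tolerances for peptides below /
    above ``small_mass_cutoff``; the boundary itself counts as small. The CE
    migration-time tolerance widens linearly from ``pct_lo`` percent at
    ``t_lo`` minutes to ``pct_hi`` percent at ``t_hi`` minutes and is clamped
    outside that range. ``max_drift`` is the post-calibration QC bound on
    internal-standard migration-time drift (minutes); it is not a matching
    tolerance.
    """

    ppm_small: float = 50.0
    ppm_large: float = 75.0
    small_mass_cutoff: float = 6000.0
    pct_lo: float = 2.0
    pct_hi: float = 5.0
    t_lo: float = 19.0
    t_hi: float = 45.0
    max_drift: float = 0.45

    def __post_init__(self) -> None:
        vals = (self.ppm_small, self.ppm_large, self.small_mass_cutoff,
                self.pct_lo, self.pct_hi, self.t_lo, self.t_hi, self.max_drift)
        if not all(v > 0 for v in vals):
            raise ValidationError("all matching parameters must be positive")
        if not self.pct_lo < self.pct_hi:
            raise ValidationError("pct_lo must be < pct_hi")
        if not self.t_lo < self.t_hi:
            raise ValidationError("t_lo must be < t_hi")


def mass_tolerance(mass: float, params: MatchingParams = MatchingParams()) -> float:
    """Mass tolerance in ppm for a peptide of the given mass.

    Small peptides (mass <= ``small_mass_cutoff``, boundary inclusive) are
    matched at ``ppm_small``; larger peptides and proteins at ``ppm_large``.
    """
    if not mass > 0:
        raise ValidationError(f"mass must be > 0, got {mass}")
    return params.ppm_small if mass <= params.small_mass_cutoff else params.ppm_large


def migration_tolerance(cetime: float, params: MatchingParams = MatchingParams()) -> float:
    """Accepted migration-time deviation (percent) at the given CE time.

    Linear interpolation between ``pct_lo`` at ``t_lo`` and ``pct_hi`` at
    ``t_hi``, clamped to those endpoints outside the range.
    """
    if not cetime > 0:
        raise ValidationError(f"cetime must be > 0, got {cetime}")
    frac = (cetime - params.t_lo) / (params.t_hi - params.t_lo)
    frac = min(max(frac, 0.0), 1.0)
    return params.pct_lo + (params.pct_hi - params.pct_lo) * frac


# ---------------------------------------------------------------------------
# TSV I/O


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: column {column!r} is not numeric: {value!r}")


def read_profiles(path: str | Path) -> list[SampleProfile]:
    """Read sample profiles from a long-format TSV.

    Header: ``sample_id fluid group mass cetime intensity`` with optional
    ``sequence parent_id start end``. Row numbers in error messages are
    1-based file lines (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    profiles: dict[str, SampleProfile] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        mass = _parse_float(row["mass"], "mass", line)
        cetime = _parse_float(row["cetime"], "cetime", line)
        intensity = _parse_float(row["intensity"], "intensity", line)
        if intensity < 0:
            raise ValidationError(f"row {line}: negative intensity {intensity}")
        kwargs: dict = {}
        if "sequence" in df.columns and row.get("sequence", ""):
            kwargs["sequence"] = row["sequence"]
        if "parent_id" in df.columns and row.get("parent_id", ""):
            kwargs["parent_id"] = row["parent_id"]
        for col in ("start", "end"):
            if col in df.columns and row.get(col, ""):
                kwargs[col] = int(_parse_float(row[col], col, line))
        try:
            rec = PeptideRecord(mass=mass, cetime=cetime, intensity=intensity, **kwargs)
        except ValidationError as exc:
            raise ValidationError(f"row {line}: {exc}") from exc
        sid = row["sample_id"]
        if sid not in profiles:
            profiles[sid] = SampleProfile(
                sample_id=sid, fluid=row["fluid"], group=row["group"], peptides=[rec]
            )
        else:
            prof = profiles[sid]
            if prof.fluid != row["fluid"] or prof.group != row["group"]:
                raise ValidationError(
                    f"row {line}: inconsistent fluid/group for sample {sid!r}"
                )
            prof.peptides.append(rec)
    if not profiles:
        raise ValidationError("non-empty profile required: file contains no peptide rows")
    return list(profiles.values())


def write_profiles(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    """Write profiles to the long-format TSV read by :func:`read_profiles`."""
    rows = []
    for prof in profiles:
        for p in prof.peptides:
            rows.append({
                "sample_id": prof.sample_id, "fluid": prof.fluid, "group": prof.group,
                "mass": p.mass, "cetime": p.cetime, "intensity": p.intensity,
                "sequence": p.sequence or "", "parent_id": p.parent_id or "",
                "start": "" if p.start is None else p.start,
                "end": "" if p.end is None else p.end,
            })
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS) + list(OPTIONAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Internal-standard normalization


def normalize_profile(
    profile: SampleProfile,
    standards: Sequence[PeptideRecord],
    params: MatchingParams = MatchingParams(),
    local: bool = False,
    n_windows: int = 4,
) -> SampleProfile:
    """Normalize ion signals against internal-standard peptides.

    Each standard carries its reference intensity; standards are located in
    the profile by the usual mass/migration-time tolerances. A linear
    regression of observed log-intensity on reference log-intensity over the
    matched standards yields ``log I_obs = a + b log I_ref``; every peptide
    intensity is corrected by the inverse map ``exp((log I - a) / b)``, so the
    standards land on their reference values with zero residual slope. When
    the references carry (numerically) no spread, the slope is fixed at 1 and
    only the offset is corrected.

    With ``local=True`` a second, piecewise pass over ``n_windows``
    equal-width migration-time windows removes any residual per-window offset
    (windows with fewer than two matched standards are left untouched).

    Raises
    ------
    NormalizationError
        If fewer than three standards are matched in the profile.
    """
    matched: list[tuple[int, PeptideRecord]] = []  # (peptide index, standard)
    used: set[int] = set()
    for std in standards:
        best, best_dev = None, np.inf
        for i, pep in enumerate(profile.peptides):
            if i in used:
                continue
            dm = abs(pep.mass - std.mass) / std.mass * 1e6
            dt = abs(pep.cetime - std.cetime) / std.cetime * 100.0
            if dm <= mass_tolerance(std.mass, params) and dt <= migration_tolerance(std.cetime, params):
                dev = dm / mass_tolerance(std.mass, params) + dt / migration_tolerance(std.cetime, params)
                if dev < best_dev:
                    best, best_dev = i, dev
        if best is not None:
            used.add(best)
            matched.append((best, std))
    if len(matched) < 3:
        raise NormalizationError(
            f"sample {profile.sample_id!r}: only {len(matched)} internal standards "
            "matched; >= 3 required"
        )

    drift = max(abs(profile.peptides[i].cetime - std.cetime) for i, std in matched)
    if drift >= params.max_drift:
        warnings.warn(
            f"sample {profile.sample_id!r}: internal-standard migration drift "
            f"{drift:.3f} min exceeds QC bound {params.max_drift} min",
            stacklevel=2,
        )

    log_obs = np.log([profile.peptides[i].intensity for i, _ in matched])
    log_ref = np.log([std.intensity for _, std in matched])
    if np.ptp(log_ref) < 1e-12:
        b, a = 1.0, float(np.mean(log_obs - log_ref))
    else:
        b, a = np.polyfit(log_ref, log_obs, 1)
        if abs(b) < 1e-12:
            raise NormalizationError("degenerate standard regression (zero slope)")

    def correct(intensity: float) -> float:
        return float(np.exp((np.log(intensity) - a) / b)) if intensity > 0 else 0.0

    peptides = [replace(p, intensity=correct(p.intensity)) for p in profile.peptides]

    if local:
        times = np.array([p.cetime for p in peptides])
        edges = np.linspace(times.min(), times.max() + 1e-9, n_windows + 1)
        for w in range(n_windows):
            in_win = [
                (i, std) for i, std in matched
                if edges[w] <= peptides[i].cetime < edges[w + 1]
            ]
            if len(in_win) < 2:
                continue
            offset = float(np.mean([
                np.log(peptides[i].intensity) - np.log(std.intensity)
                for i, std in in_win if peptides[i].intensity > 0
            ]))
            for j, p in enumerate(peptides):
                if edges[w] <= p.cetime < edges[w + 1] and p.intensity > 0:
                    peptides[j] = replace(p, intensity=float(np.exp(np.log(p.intensity) - offset)))

    return SampleProfile(profile.sample_id, profile.fluid, profile.group, peptides)


# ---------------------------------------------------------------------------
# Cross-sample matching


class ProfileMatrix:
    """Peptide x sample intensity matrix with per-marker consensus metadata.

    Attributes
    ----------
    markers : pandas.DataFrame
        Indexed by marker id; columns ``mass``, ``cetime`` (consensus values)
        and, where available, ``sequence``, ``parent_id``, ``start``, ``end``.
    intensities : pandas.DataFrame
        Marker x sample matrix; a peptide absent from a sample is 0.
    fluid : str
    """

    def __init__(self, markers: pd.DataFrame, intensities: pd.DataFrame, fluid: str):
        if not markers.index.equals(intensities.index):
            raise ValidationError("marker metadata and intensity rows must align")
        if (intensities.values < 0).any():
            raise ValidationError("intensities must be non-negative")
        self.markers = markers
        self.intensities = intensities
        self.fluid = fluid

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<ProfileMatrix fluid={self.fluid} markers={len(self.markers)} "
                f"samples={self.intensities.shape[1]}>")


class _Cluster:
    __slots__ = ("mass", "cetime", "weight", "members", "meta")

    def __init__(self, sample: str, pep: PeptideRecord):
        self.mass = pep.mass
        self.cetime = pep.cetime
        self.weight = max(pep.intensity, 1e-30)
        self.members: list[tuple[str, PeptideRecord]] = [(sample, pep)]
        self.meta = pep  # highest-intensity member (seed) carries annotation

    def add(self, sample: str, pep: PeptideRecord) -> None:
        w = max(pep.intensity, 1e-30)
        total = self.weight + w
        self.mass = (self.mass * self.weight + pep.mass * w) / total
        self.cetime = (self.cetime * self.weight + pep.cetime * w) / total
        self.weight = total
        self.members.append((sample, pep))


def match_peptides(
    profiles: Sequence[SampleProfile],
    params: MatchingParams = MatchingParams(),
) -> ProfileMatrix:
    """Match peptides across samples into a :class:`ProfileMatrix`.

    Peptides from all samples are clustered greedily in descending intensity
    order (ties broken by ascending mass, then migration time and sample id,
    so the result is independent of input order). A peptide joins an existing
    cluster iff its relative mass deviation from the cluster consensus is
    within :func:`mass_tolerance` at the consensus mass AND its relative
    migration-time deviation is within :func:`migration_tolerance` at the
    consensus time; among admissible clusters the one with the smallest
    combined relative deviation wins. Consensus mass and time are
    intensity-weighted means over members. If one sample contributes several
    peptides to a cluster their signals are summed.
    """
    if len(profiles) < 2:
        raise ValidationError("matching requires at least 2 profiles")
    fluids = {p.fluid for p in profiles}
    if len(fluids) > 1:
        raise ValidationError(f"all profiles must share one fluid, got {sorted(fluids)}")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample ids must be unique within a cohort")

    items = [
        (-pep.intensity, pep.mass, pep.cetime, prof.sample_id, pep)
        for prof in profiles for pep in prof.peptides
    ]
    items.sort(key=lambda t: t[:4])

    clusters: list[_Cluster] = []
    order: list[float] = []   # sorted consensus masses
    index: list[int] = []     # cluster index aligned with `order`
    max_rel = params.ppm_large * 1e-6 * 2

    for _, mass, cetime, sample, pep in items:
        lo = bisect.bisect_left(order, mass * (1 - max_rel))
        hi = bisect.bisect_right(order, mass * (1 + max_rel))
        best, best_dev, best_pos = None, np.inf, None
        for pos in range(lo, hi):
            c = clusters[index[pos]]
            tol_m = mass_tolerance(c.mass, params)
            tol_t = migration_tolerance(c.cetime, params)
            dm = abs(mass - c.mass) / c.mass * 1e6
            dt = abs(cetime - c.cetime) / c.cetime * 100.0
            if dm <= tol_m and dt <= tol_t:
                dev = dm / tol_m + dt / tol_t
                if dev < best_dev:
                    best, best_dev, best_pos = index[pos], dev, pos
        if best is None:
            c = _Cluster(sample, pep)
            clusters.append(c)
            pos = bisect.bisect_left(order, c.mass)
            order.insert(pos, c.mass)
            index.insert(pos, len(clusters) - 1)
        else:
            c = clusters[best]
            order.pop(best_pos)
            index.pop(best_pos)
            c.add(sample, pep)
            pos = bisect.bisect_left(order, c.mass)
            order.insert(pos, c.mass)
            index.insert(pos, best)

    clusters.sort(key=lambda c: (c.mass, c.cetime))
    width = max(4, len(str(len(clusters))))
    marker_ids = [f"pep{i + 1:0{width}d}" for i in range(len(clusters))]
    meta = pd.DataFrame(
        {
            "mass": [c.mass for c in clusters],
            "cetime": [c.cetime for c in clusters],
            "sequence": [c.meta.sequence for c in clusters],
            "parent_id": [c.meta.parent_id for c in clusters],
            "start": [c.meta.start for c in clusters],
            "end": [c.meta.end for c in clusters],
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    mat = np.zeros((len(clusters), len(ids)))
    col = {sid: j for j, sid in enumerate(ids)}
    for i, c in enumerate(clusters):
        for sample, pep in c.members:
            mat[i, col[sample]] += pep.intensity
    intensities = pd.DataFrame(mat, index=meta.index, columns=ids)
    return ProfileMatrix(meta, intensities, fluid=profiles[0].fluid)


def write_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix as TSV (marker metadata columns, then samples)."""
    out = matrix.markers.join(matrix.intensities)
    out.insert(0, "fluid", matrix.fluid)
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> ProfileMatrix:
    """Read a profile matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["mass", "cetime", "sequence", "parent_id", "start", "end"]
    missing = [c for c in ("fluid", "mass", "cetime") if c not in df.columns]
    if missing:
        raise FormatError(f"matrix file lacks column(s): {', '.join(missing)}")
    fluid = str(df["fluid"].iloc[0])
    markers = df[meta_cols].copy()
    markers["sequence"] = markers["sequence"].where(markers["sequence"].notna(), None)
    markers["parent_id"] = markers["parent_id"].where(markers["parent_id"].notna(), None)
    sample_cols = [c for c in df.columns if c not in meta_cols + ["fluid"]]
    intensities = df[sample_cols].astype(float)
    return ProfileMatrix(markers, intensities, fluid=fluid)
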
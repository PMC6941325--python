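"""End-to-end driver: profiles -> matrix -> protease mapping -> activity table.

Chains the stages exactly as they are applied to a patient cohort: match the
per-sample peptide lists into a profile matrix, extract the terminal
cleavage motifs of all sequenced markers, map them (and random decoys)
against the protease specificity matrices, apply the decoy-calibrated
PPV/site filter, integrate substrate ion signals per patient and compare
case against control groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .activity import compare_groups, patient_activity
from .errors import ValidationError
from .mapping import (CleavageMotif, PPVReport, ProteaseAssignment,
                      SpecificityMatrix, compute_ppv, extract_terminal_motifs,
                      generate_decoys, map_proteases)
from .profiles import MatchingParams, PeptideRecord, ProfileMatrix, SampleProfile, match_peptides

__all__ = ["PipelineResult", "marker_motifs", "run_protease_pipeline"]


@dataclass
class PipelineResult:
    matrix: ProfileMatrix
    motifs: list[CleavageMotif]
    assignments: list[ProteaseAssignment]
    ppv_reports: list[PPVReport]
    retained: list[str]
    activity: pd.DataFrame
    comparison: pd.DataFrame


def marker_motifs(matrix: ProfileMatrix, proteome: Mapping[str, str]
                  ) -> list[CleavageMotif]:
    """Terminal motifs of every sequenced marker in a profile matrix."""
    motifs: list[CleavageMotif] = []
    for marker_id, row in matrix.markers.iterrows():
        if row["sequence"] is None or pd.isna(row["parent_id"]) or row["parent_id"] is None:
            continue
        parent = proteome.get(row["parent_id"])
        if parent is None:
            raise ValidationError(f"unknown parent protein {row['parent_id']!r}")
        rec = PeptideRecord(
            mass=float(row["mass"]), cetime=float(row["cetime"]), intensity=0.0,
            sequence=row["sequence"], parent_id=row["parent_id"],
            start=int(row["start"]), end=int(row["end"]),
        )
        motifs.extend(extract_terminal_motifs(rec, parent, marker_id=marker_id))
    return motifs


def run_protease_pipeline(
    profiles: Sequence[SampleProfile],
    proteome: Mapping[str, str],
    matrices: Sequence[SpecificityMatrix],
    labels: Mapping[str, str],
    n_decoys: int = 1000,
    seed: int = 0,
    params: MatchingParams = MatchingParams(),
    apply_ppv_filter: bool = True,
) -> PipelineResult:
    """Run matching, mapping, PPV filtering and activity comparison.

    ``labels`` maps sample ids to "case"/"control". With
    ``apply_ppv_filter`` (default) the activity table covers only proteases
    retained by the PPV > 0.65 / >= 4 sites rule.
    """
    matrix = match_peptides(profiles, params)
    motifs = marker_motifs(matrix, proteome)
    if not motifs:
        raise ValidationError("no sequenced markers with parent coordinates")
    decoys = [
        CleavageMotif(f"decoy{i:05d}", "N", seq)
        for i, seq in enumerate(generate_decoys(n_decoys, seed))
    ]
    assignments = map_proteases(motifs, matrices)
    decoy_assignments = map_proteases(decoys, matrices) if decoys else []
    reports = compute_ppv(assignments, decoy_assignments,
                          n_targets=len(motifs), n_decoys=len(decoys))
    retained = [r.protease_id for r in reports if r.retained]
    kept = ([a for a in assignments if a.protease_id in retained]
            if apply_ppv_filter else assignments)
    activity = patient_activity(matrix, kept) if kept else pd.DataFrame(
        columns=["sample_id", "protease_id", "activity"])
    comparison = (compare_groups(activity, labels)
                  if len(activity) else pd.DataFrame())
    return PipelineResult(matrix, motifs, assignments, reports, retained,
                          activity, comparison)
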
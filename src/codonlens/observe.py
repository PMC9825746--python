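"""Map alignment correspondences back to genomic codons.

Each surviving match correspondence (one profile consensus column aligned
to one translated residue) is attributed to the genomic codon that residue
came from, carrying the column's match-emission vector.  Grouping these by
the 64 codon types yields the observation sets that codon inference
consumes; the grouped file is the pipeline's resumable checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignmentSegment
from .codes import (
    CODONS,
    FrameTranslation,
    codon_index,
    parse_target_id,
    reverse_complement,
    standard_code,
)
from .errors import CoordinateError, UnknownProfileError
from .profiles import ExclusionList, ProfileHMM, floor_and_normalize


@dataclass(frozen=True)
class CodonObservation:
    """One consensus column attributed to one genomic codon."""

    codon_idx: int
    emission: np.ndarray = field(repr=False)
    profile_name: str = ""
    consensus_column: int = 0
    source_id: str = ""
    genomic_start: int = 0
    strand: str = "+"

    @property
    def codon(self) -> str:
        return CODONS[self.codon_idx]


@dataclass
class ObservationSet:
    """Per-codon lists of observations, in deterministic pipeline order."""

    by_codon: list[list[CodonObservation]] = field(
        default_factory=lambda: [[] for _ in range(64)]
    )

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(lst) for lst in self.by_codon], dtype=int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, obs: CodonObservation) -> None:
        self.by_codon[obs.codon_idx].append(obs)

    def __iter__(self):
        for lst in self.by_codon:
            yield from lst


def residue_to_codon(
    translation: FrameTranslation, residue_pos: int, source_seq: str
) -> tuple[str, int]:
    """Genomic codon behind residue ``residue_pos`` of a frame translation.

    Returns the codon as read on the coding strand together with the
    forward-strand coordinate of its lowest base.  Raises
    :class:`CoordinateError` if the position falls outside the source —
    which would indicate an inconsistency between the aligner's target
    and the translation.
    """
    if not 0 <= residue_pos < len(translation.protein):
        raise CoordinateError(
            f"residue {residue_pos} outside translation "
            f"{translation.target_id} (length {len(translation.protein)})"
        )
    L = len(source_seq)
    offset = translation.frame + 3 * residue_pos
    if offset + 3 > L:
        raise CoordinateError(
            f"codon for residue {residue_pos} of {translation.target_id} "
            f"overruns the source sequence"
        )
    if translation.strand == "+":
        start = offset
        codon = source_seq[start: start + 3]
    else:
        start = L - offset - 3
        codon = reverse_complement(source_seq[start: start + 3])
    return codon, start


def _segment_codon_positions(
    segment: AlignmentSegment, translations: dict[str, FrameTranslation]
) -> tuple[str, str, list[int]]:
    tr = translations[segment.target_id]
    return tr.source_id, tr.strand, [
        tr.codon_coords[pos] for _, pos in segment.column_map
    ]


def filter_segments(
    segments: list[AlignmentSegment],
    profiles: dict[str, ProfileHMM],
    translations: dict[str, FrameTranslation],
    exclusion: ExclusionList | None = None,
    significance_threshold: float | None = None,
    significance_mode: str = "bits",
    overlap_policy: str = "best",
) -> list[AlignmentSegment]:
    """Apply exclusion, significance and overlap filters to segments.

    ``significance_mode`` is ``"bits"`` (keep score >= threshold, for the
    internal aligner) or ``"evalue"`` (keep significance <= threshold,
    for external search output).  The default overlap policy attributes a
    genomic codon claimed by two same-strand segments on the same source
    to the higher-scoring one only (ties: earlier segment); opposite
    strands are left alone since genuinely overlapping genes exist.
    """
    exclusion = exclusion or ExclusionList()
    kept = []
    for seg in segments:
        prof = profiles.get(seg.profile_name)
        if prof is None:
            raise UnknownProfileError(
                f"segment references unknown profile {seg.profile_name!r}"
            )
        if exclusion.excludes(prof):
            continue
        if significance_threshold is not None:
            if significance_mode == "bits":
                if seg.score < significance_threshold:
                    continue
            elif significance_mode == "evalue":
                if seg.significance > significance_threshold:
                    continue
            else:
                raise ValueError(
                    f"unknown significance mode {significance_mode!r}"
                )
        kept.append(seg)
    if overlap_policy == "keep-all":
        return kept
    if overlap_policy != "best":
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")

    # Higher score claims each (source, strand, codon start) first.
    order = sorted(
        range(len(kept)), key=lambda i: (-kept[i].score, i)
    )
    claimed: set[tuple[str, str, int]] = set()
    trimmed: dict[int, AlignmentSegment] = {}
    for i in order:
        seg = kept[i]
        source_id, strand, starts = _segment_codon_positions(seg, translations)
        new_map = []
        for (col, pos), start in zip(seg.column_map, starts):
            key = (source_id, strand, start)
            if key in claimed:
                continue
            claimed.add(key)
            new_map.append((col, pos))
        if new_map:
            trimmed[i] = AlignmentSegment(
                profile_name=seg.profile_name,
                target_id=seg.target_id,
                score=seg.score,
                significance=seg.significance,
                column_map=new_map,
            )
    return [trimmed[i] for i in sorted(trimmed)]


def collect_observations(
    segments: list[AlignmentSegment],
    profiles: dict[str, ProfileHMM],
    source_seqs: dict[str, str],
    translations: dict[str, FrameTranslation],
) -> ObservationSet:
    """Attribute every match correspondence to its genomic codon.

    Codons containing non-ACGT bases are skipped; everything else appends
    one :class:`CodonObservation` carrying the consensus column's
    emission row, in segment order then column order.
    """
    obs_set = ObservationSet()
    code = standard_code()
    for seg in segments:
        prof = profiles.get(seg.profile_name)
        if prof is None:
            raise UnknownProfileError(
                f"segment references unknown profile {seg.profile_name!r}"
            )
        tr = translations[seg.target_id]
        seq = source_seqs[tr.source_id]
        for col, pos in seg.column_map:
            codon, start = residue_to_codon(tr, pos, seq)
            if any(b not in "ACGT" for b in codon):
                continue
            obs_set.add(
                CodonObservation(
                    codon_idx=codon_index(codon),
                    emission=prof.match_emissions[col - 1],
                    profile_name=seg.profile_name,
                    consensus_column=col,
                    source_id=tr.source_id,
                    genomic_start=start,
                    strand=tr.strand,
                )
            )
    return obs_set


# ---------------------------------------------------------------------------
# Observation checkpoint file
# ---------------------------------------------------------------------------

_OBS_HEADER = (
    "#codon\tprofile\tcolumn\tsource_id\tgenomic_start\tstrand\temissions"
)


def write_observations(obs_set: ObservationSet, path: str | Path) -> None:
    """Grouped observation file: one row per observation, 5-decimal emissions."""
    with open(path, "w") as fh:
        fh.write(_OBS_HEADER + "\n")
        for obs in obs_set:
            em = ",".join(f"{v:.5f}" for v in obs.emission)
            fh.write(
                f"{obs.codon}\t{obs.profile_name}\t{obs.consensus_column}\t"
                f"{obs.source_id}\t{obs.genomic_start}\t{obs.strand}\t{em}\n"
            )


def read_observations(path: str | Path) -> ObservationSet:
    """Read the checkpoint back; emission rows are renormalised."""
    obs_set = ObservationSet()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            codon, prof, col, src, start, strand, em = (
                line.rstrip("\n").split("\t")
            )
            emission = floor_and_normalize(
                np.array([float(v) for v in em.split(",")])
            )
            obs_set.add(
                CodonObservation(
                    codon_idx=codon_index(codon),
                    emission=emission,
                    profile_name=prof,
                    consensus_column=int(col),
                    source_id=src,
                    genomic_start=int(start),
                    strand=strand,
                )
            )
    return obs_set
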
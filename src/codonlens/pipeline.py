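"""Staged pipeline: align -> process -> infer, with file checkpoints.

Each stage reads the previous stage's checkpoint so runs are resumable;
the bundled run is literally the three stages in sequence, which makes
staged and bundled outputs byte-identical by construction.  All stages
are deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import align as _align
from . import observe as _observe
from .codes import (
    FrameTranslation,
    GeneticCode,
    ncbi_table,
    read_fasta,
    six_frame_translate,
)
from .errors import InvalidSequenceError
from .infer import (
    CodonPosterior,
    InferenceConfig,
    infer_code,
    write_code_string,
    write_diff,
    write_report,
)
from .profiles import ExclusionList, load_exclusion_list, read_hmmer3_profiles

log = logging.getLogger("codonlens")


@dataclass
class StageCounters:
    """Per-stage counters; the observable surface for filter behaviour."""

    sequences_read: int = 0
    frames_translated: int = 0
    segments_found: int = 0
    segments_kept: int = 0
    observations_total: int = 0


def _load_inputs(genome_fasta, profile_db):
    sources = dict(read_fasta(genome_fasta))
    if not sources:
        raise InvalidSequenceError(f"no sequences in {genome_fasta}")
    profiles = read_hmmer3_profiles(profile_db)
    return sources, {p.name: p for p in profiles}


def _translations(sources) -> dict[str, FrameTranslation]:
    out: dict[str, FrameTranslation] = {}
    for source_id, seq in sources.items():
        for tr in six_frame_translate(seq, source_id=source_id):
            out[tr.target_id] = tr
    return out


def alignments_path(prefix: str | Path) -> Path:
    return Path(f"{prefix}.alignments.tsv")


def observations_path(prefix: str | Path) -> Path:
    return Path(f"{prefix}.observations.tsv")


def stage_align(
    genome_fasta: str | Path,
    profile_db: str | Path,
    out_prefix: str | Path,
    aligner: str = "internal",
    min_score_bits: float = _align.DEFAULT_MIN_SCORE_BITS,
    workers: int = 1,
    executable: str = "hmmscan",
) -> Path:
    """Six-frame translate the genome and align every profile to it."""
    sources, profiles = _load_inputs(genome_fasta, profile_db)
    translations = _translations(sources)
    counters = StageCounters(
        sequences_read=len(sources), frames_translated=len(translations)
    )
    if aligner == "internal":
        segments = _align.align_profiles_to_translations(
            profiles.values(), translations.values(), min_score_bits
        )
    elif aligner == "external":
        out_dir = Path(f"{out_prefix}.hmmscan")
        trans_fasta = out_dir / "translations.faa"
        out_dir.mkdir(parents=True, exist_ok=True)
        from .codes import write_fasta

        write_fasta(
            [(t.target_id, t.protein.replace("*", "X"))
             for t in translations.values() if len(t.protein) >= 5],
            trans_fasta,
        )
        outputs = _align.run_external_search(
            profile_db, trans_fasta, out_dir, n_workers=workers,
            executable=executable,
        )
        segments = _align.parse_search_output_files(outputs)
    else:
        raise ValueError(f"unknown aligner {aligner!r}")
    counters.segments_found = len(segments)
    log.info(
        "align: %d sequences, %d frames, %d segments",
        counters.sequences_read, counters.frames_translated,
        counters.segments_found,
    )
    out = alignments_path(out_prefix)
    _align.write_segments(segments, out)
    return out


def stage_process(
    genome_fasta: str | Path,
    profile_db: str | Path,
    out_prefix: str | Path,
    exclusion_path: str | Path | None = None,
    significance_threshold: float | None = None,
    significance_mode: str = "bits",
    overlap_policy: str = "best",
) -> Path:
    """Filter segments and group match correspondences by codon."""
    sources, profiles = _load_inputs(genome_fasta, profile_db)
    translations = _translations(sources)
    segments = _align.read_segments(alignments_path(out_prefix))
    exclusion = (
        load_exclusion_list(exclusion_path) if exclusion_path else ExclusionList()
    )
    kept = _observe.filter_segments(
        segments, profiles, translations, exclusion,
        significance_threshold, significance_mode, overlap_policy,
    )
    obs_set = _observe.collect_observations(kept, profiles, sources, translations)
    log.info(
        "process: %d/%d segments kept, %d observations",
        len(kept), len(segments), obs_set.total,
    )
    out = observations_path(out_prefix)
    _observe.write_observations(obs_set, out)
    return out


def stage_infer(
    profile_db: str | Path,
    out_prefix: str | Path,
    threshold: float = 0.9999,
    reference_table: int = 1,
) -> tuple[GeneticCode, list[CodonPosterior]]:
    """Decide each codon's meaning and write the code string and reports."""
    profiles = read_hmmer3_profiles(profile_db)
    background = np.mean([p.background for p in profiles], axis=0)
    background = background / background.sum()
    obs_set = _observe.read_observations(observations_path(out_prefix))
    config = InferenceConfig(threshold=threshold, background=background)
    code, posteriors = infer_code(obs_set, config)
    write_code_string(code, Path(f"{out_prefix}.genetic_code.txt"))
    write_report(posteriors, Path(f"{out_prefix}.report.tsv"))
    write_diff(code, ncbi_table(reference_table), Path(f"{out_prefix}.diff.tsv"))
    decided = sum(cp.decision != "?" for cp in posteriors)
    log.info("infer: %d/64 codons decided", decided)
    return code, posteriors


def run_pipeline(
    genome_fasta: str | Path,
    profile_db: str | Path,
    out_prefix: str | Path,
    aligner: str = "internal",
    min_score_bits: float = _align.DEFAULT_MIN_SCORE_BITS,
    significance_threshold: float | None = None,
    significance_mode: str | None = None,
    exclusion_path: str | Path | None = None,
    threshold: float = 0.9999,
    workers: int = 1,
    reference_table: int = 1,
) -> tuple[GeneticCode, list[CodonPosterior]]:
    """The bundled three-stage run (identical artifacts to staged runs)."""
    if significance_mode is None:
        significance_mode = "bits" if aligner == "internal" else "evalue"
    if significance_threshold is None:
        significance_threshold = (
            min_score_bits if significance_mode == "bits"
            else _align.DEFAULT_MAX_EVALUE
        )
    stage_align(
        genome_fasta, profile_db, out_prefix,
        aligner=aligner, min_score_bits=min_score_bits, workers=workers,
    )
    stage_process(
        genome_fasta, profile_db, out_prefix,
        exclusion_path=exclusion_path,
        significance_threshold=significance_threshold,
        significance_mode=significance_mode,
    )
    return stage_infer(
        profile_db, out_prefix,
        threshold=threshold, reference_table=reference_table,
    )
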
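"""End-to-end orchestration: inputs -> prefilters -> degradome alignment ->
candidate generation -> region filtering -> duplex alignment -> confidence
filters -> results CSV.

The prediction path contains no randomness: given fixed inputs and
configuration, repeated runs produce byte-identical CSVs.  Normalized
abundances are reads-per-million over the *retained* (post-filter) library
total, which is logged with every run.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional, Sequence

from . import confidence, degradome, prefilter, seqio
from .duplex import align_duplex, render_duplex
from .rules import TargetingRuleSet, extract_regions, preset, three_stage_filter
from .seqio import ReadLibrary, Transcript

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedInteraction:
    """One predicted sRNA x transcript cleavage interaction."""

    srna_name: str
    srna_sequence: str
    srna_abundance_raw: int
    srna_abundance_norm: float
    transcript_id: str
    cleavage_position: int
    category: int
    peak_abundance_raw: int
    peak_abundance_weighted: float
    peak_abundance_norm: float
    alignment_score: float
    duplex: str
    mfe: float
    mfe_ratio: float
    p_value: float

    def as_row(self) -> list:
        return [
            self.srna_name,
            self.srna_sequence,
            self.srna_abundance_raw,
            f"{self.srna_abundance_norm:.4f}",
            self.transcript_id,
            self.cleavage_position,
            self.category,
            self.peak_abundance_raw,
            f"{self.peak_abundance_weighted:.4f}",
            f"{self.peak_abundance_norm:.4f}",
            f"{self.alignment_score:g}",
            self.duplex,
            f"{self.mfe:.2f}",
            f"{self.mfe_ratio:.4f}",
            f"{self.p_value:.6g}",
        ]


def normalize(raw: int, library_total: int) -> float:
    """Reads-per-million: raw * 10^6 / library total."""
    if library_total <= 0:
        raise ValueError("library total must be > 0")
    return raw * 1_000_000 / library_total


def predict_targets(
    transcripts: list[Transcript],
    srna_lib: ReadLibrary,
    deg_lib: ReadLibrary,
    rules: TargetingRuleSet,
    allowed_categories: frozenset[int] = frozenset({0, 1, 2, 3}),
    min_fragment_abundance: int = 1,
    deg_len_range: tuple[int, int] = (19, 21),
    mfe_ratio_cutoff: Optional[float] = 0.7,
    pvalue_cutoff: Optional[float] = None,
    srna_names: Optional[dict[str, str]] = None,
    energy_backend: str = "builtin",
    bypass_region_filter: bool = False,
) -> list[PredictedInteraction]:
    """Core prediction over already-filtered libraries.

    ``bypass_region_filter`` sends every candidate straight to the duplex
    aligner; because the three-stage filter is conservative, the result set
    is identical either way (the flag exists to verify exactly that).
    """
    srna_names = srna_names or {}
    index = degradome.build_fragment_index(deg_lib, *deg_len_range)
    profiles = degradome.align_degradome(transcripts, index)
    by_id = {t.id: t for t in transcripts}
    all_candidates: list[degradome.TargetCandidate] = []
    for tid in sorted(profiles):
        profile = degradome.assign_categories(profiles[tid])
        all_candidates.extend(
            degradome.extract_candidates(
                by_id[tid], profile, allowed_categories, min_fragment_abundance
            )
        )
    groups = degradome.group_by_tr2(all_candidates)

    srna_total = srna_lib.total_abundance
    deg_total = deg_lib.total_abundance
    results: list[PredictedInteraction] = []
    for srna in sorted(srna_lib.records):
        regions = extract_regions(srna)
        if bypass_region_filter:
            survivors = list(all_candidates)
        else:
            survivors = three_stage_filter(regions, groups, rules)
        n_evaluated = Counter(c.transcript_id for c in survivors)
        for cand in survivors:
            alignment = align_duplex(srna, cand, rules)
            if alignment is None:
                continue
            ratio = confidence.mfe_ratio(alignment, backend=energy_backend)
            if mfe_ratio_cutoff is not None and ratio < mfe_ratio_cutoff:
                continue
            p = confidence.site_pvalue(
                cand.category,
                profiles[cand.transcript_id],
                n_evaluated[cand.transcript_id],
            )
            if pvalue_cutoff is not None and p > pvalue_cutoff:
                continue
            results.append(
                PredictedInteraction(
                    srna_name=srna_names.get(srna, srna),
                    srna_sequence=srna,
                    srna_abundance_raw=srna_lib.records[srna],
                    srna_abundance_norm=normalize(srna_lib.records[srna], srna_total),
                    transcript_id=cand.transcript_id,
                    cleavage_position=cand.cleavage_pos,
                    category=cand.category,
                    peak_abundance_raw=cand.abundance,
                    peak_abundance_weighted=cand.weighted_abundance,
                    peak_abundance_norm=normalize(cand.abundance, deg_total),
                    alignment_score=alignment.score,
                    duplex=render_duplex(alignment),
                    mfe=confidence.alignment_mfe(alignment, backend=energy_backend),
                    mfe_ratio=ratio,
                    p_value=p,
                )
            )
    results.sort(
        key=lambda r: (r.transcript_id, r.cleavage_position, r.srna_sequence)
    )
    return results


@dataclass
class RunConfig:
    """File-level configuration of a full run."""

    transcriptome: Optional[str] = None
    gff3: Optional[str] = None
    genome: Optional[str] = None
    include_utrs: bool = True
    srna_paths: Sequence[str] = ()
    degradome_paths: Sequence[str] = ()
    rules: TargetingRuleSet | str = "allen"
    min_srna_abundance: int = 5
    srna_len_range: tuple[int, int] = (19, 24)
    deg_len_range: tuple[int, int] = (19, 21)
    allowed_categories: frozenset[int] = frozenset({0, 1, 2, 3})
    mfe_ratio_cutoff: Optional[float] = 0.7
    pvalue_cutoff: Optional[float] = None
    conservation: bool = False
    genome_filter: Optional[str] = None
    low_complexity: bool = True
    energy_backend: str = "builtin"
    threads: int = 1
    out_dir: str = "."


def _resolve_rules(spec: TargetingRuleSet | str) -> TargetingRuleSet:
    if isinstance(spec, TargetingRuleSet):
        return spec
    if spec in ("allen", "fc", "fahlgren_carrington"):
        return preset(spec)
    return TargetingRuleSet.from_json(spec)


def _prepare_srna_lib(
    lib: ReadLibrary, config: RunConfig, genome: Optional[list[Transcript]]
) -> ReadLibrary:
    lib = prefilter.filter_ambiguous(lib)
    if config.low_complexity:
        lib = prefilter.filter_low_complexity(lib)
    lib = prefilter.filter_size_abundance(
        lib, *config.srna_len_range, config.min_srna_abundance
    )
    if genome is not None:
        lib = prefilter.filter_genome_match(lib, genome)
    return lib


def _prepare_deg_lib(lib: ReadLibrary, config: RunConfig) -> ReadLibrary:
    lib = prefilter.filter_ambiguous(lib)
    if config.low_complexity:
        lib = prefilter.filter_low_complexity(lib)
    return lib


def run(config: RunConfig) -> dict[str, list[PredictedInteraction]]:
    """Execute a full analysis; one results CSV per degradome library,
    plus a conservation-intersected summary when replicates are supplied.

    Returns the per-degradome-library result lists keyed by library name.
    """
    if config.gff3 is not None:
        if config.genome is None:
            raise ValueError(
                "a genome FASTA must be provided when the reference is GFF3"
            )
        transcripts = seqio.extract_transcripts_gff3(
            config.gff3, config.genome, include_utrs=config.include_utrs
        )
    elif config.transcriptome is not None:
        transcripts = seqio.read_transcriptome_fasta(config.transcriptome)
    else:
        raise ValueError("either a transcriptome FASTA or a GFF3 reference is required")
    if not config.srna_paths or not config.degradome_paths:
        raise ValueError("at least one sRNA and one degradome library are required")

    rules = _resolve_rules(config.rules)
    genome_records = (
        seqio.read_transcriptome_fasta(config.genome_filter)
        if config.genome_filter
        else None
    )

    srna_libs = [
        _prepare_srna_lib(seqio.read_redundant_fasta(p), config, genome_records)
        for p in config.srna_paths
    ]
    if config.conservation and len(srna_libs) > 1:
        srna_libs = prefilter.filter_conservation(srna_libs)
    for lib, path in zip(srna_libs, config.srna_paths):
        if not lib.records:
            raise ValueError(f"sRNA library {path} is empty after filtering")
        logger.info(
            "sRNA library %s: %d unique reads, retained total %d",
            lib.name, len(lib), lib.total_abundance,
        )
    # replicates are merged for prediction (union, summed abundance)
    merged = ReadLibrary(name="srna_merged")
    for lib in srna_libs:
        for seq, abundance in lib.records.items():
            merged.add(seq, abundance)

    deg_libs = [
        _prepare_deg_lib(seqio.read_redundant_fasta(p), config)
        for p in config.degradome_paths
    ]

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_results: dict[str, list[PredictedInteraction]] = {}
    for lib, path in zip(deg_libs, config.degradome_paths):
        if not lib.records:
            raise ValueError(f"degradome library {path} is empty after filtering")
        results = predict_targets(
            transcripts,
            merged,
            lib,
            rules,
            allowed_categories=config.allowed_categories,
            deg_len_range=config.deg_len_range,
            mfe_ratio_cutoff=config.mfe_ratio_cutoff,
            pvalue_cutoff=config.pvalue_cutoff,
            energy_backend=config.energy_backend,
        )
        all_results[lib.name] = results
        seqio.write_results_csv(results, out_dir / f"{lib.name}.results.csv")
        logger.info("library %s: %d interactions", lib.name, len(results))

    if len(deg_libs) > 1:
        # conservation summary: interactions present in every replicate,
        # keyed by the (sRNA, transcript, position) triple
        keys = None
        for results in all_results.values():
            triple = {
                (r.srna_sequence, r.transcript_id, r.cleavage_position)
                for r in results
            }
            keys = triple if keys is None else keys & triple
        first = next(iter(all_results.values()))
        summary = [
            r
            for r in first
            if (r.srna_sequence, r.transcript_id, r.cleavage_position) in keys
        ]
        seqio.write_results_csv(summary, out_dir / "conserved.results.csv")
        all_results["conserved"] = summary
    return all_results
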
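"""Model/Results interface tying the covariation pipeline together.

:class:`CovariationModel` holds the data (alignment, phylogeny, optional
reference structure) and the thresholds; :meth:`CovariationModel.fit` runs
coarse filtering, the covariation statistics (CPE via phylogenetic event
counting, MIxy, MIp) and Joint N-Best calling, returning a
:class:`CovariationResults` whose methods drive the downstream stages
(helix extension, purity, neighbor effects, evaluation) and whose
``summary()`` prints the counts a practitioner looks at first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .io import (Alignment, Phylogeny, PositionMap, ReferenceStructure,
                 build_position_map, read_alignment, read_phylogeny,
                 read_reference_structure)
from .pec import PECResult, pec_scan
from .scores import ScoreMatrix, mip, zscores
from .selection import (CandidatePair, NBestResult, coarse_filter,
                        joint_nbest, merge_calls, passed_pairs)
from .structure import (EvaluationReport, HelixExtensionResult,
                        NeighborEffect, PurityResult, evaluate_calls,
                        helix_extend, neighbor_effects, purity)
from .scores import pair_state_table

logger = logging.getLogger(__name__)


class CovariationModel:
    """Covariation analysis of an RNA alignment on a phylogeny.

    Parameters
    ----------
    alignment
        The RNA multiple sequence alignment.
    phylogeny
        Rooted (possibly multifurcating) tree with leaves mapped to
        alignment sequences; required for CPE, optional for MI-only runs.
    structure
        Reference secondary/tertiary structure for evaluation and
        neighbor-effect annotation.
    reference_sequence_id
        Alignment sequence used to map columns to reference positions;
        defaults to the structure's reference id.
    config
        Thresholds; defaults are the method's standard operating point.
    """

    def __init__(
        self,
        alignment: Alignment,
        phylogeny: Optional[Phylogeny] = None,
        structure: Optional[ReferenceStructure] = None,
        reference_sequence_id: Optional[str] = None,
        config: Optional[PipelineConfig] = None,
    ):
        self.alignment = alignment
        self.phylogeny = phylogeny
        self.structure = structure
        self.config = config or PipelineConfig()
        ref_id = reference_sequence_id or (
            structure.reference_sequence_id if structure else None
        )
        self.position_map: Optional[PositionMap] = (
            build_position_map(alignment, ref_id)
            if ref_id and ref_id in alignment.sequence_ids else None
        )

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        tree_path: Optional[str | Path] = None,
        tree_format: str = "newick",
        tree_mapping: Optional[str | Path] = None,
        structure_path: Optional[str | Path] = None,
        reference_sequence_id: Optional[str] = None,
        tertiary_tsv: Optional[str | Path] = None,
        pdb: Optional[str | Path] = None,
        config: Optional[PipelineConfig] = None,
    ) -> "CovariationModel":
        alignment = read_alignment(alignment_path)
        phylogeny = None
        if tree_path is not None:
            phylogeny = read_phylogeny(
                tree_path, format=tree_format, mapping=tree_mapping,
                alignment=alignment,
            )
        structure = None
        if structure_path is not None:
            if reference_sequence_id is None:
                raise ValueError(
                    "reference_sequence_id is required with a structure file"
                )
            structure = read_reference_structure(
                structure_path, reference_sequence_id,
                tertiary_tsv=tertiary_tsv, pdb=pdb,
            )
        return cls(alignment, phylogeny, structure,
                   reference_sequence_id, config)

    def fit(
        self,
        methods: Sequence[str] = ("CPE", "MIxy", "MIp"),
        candidate_pairs: Optional[Iterable[tuple[int, int]]] = None,
    ) -> "CovariationResults":
        """Run filtering, scoring and Joint N-Best calling.

        ``candidate_pairs`` bypasses the coarse filter when given.
        """
        cfg = self.config
        if "CPE" in methods and self.phylogeny is None:
            raise ValueError("CPE requires a phylogeny")

        if candidate_pairs is None:
            candidates = coarse_filter(
                self.alignment, entropy_tol=cfg.entropy_tol, top_k=cfg.top_k
            )
        else:
            from .scores import entropy_vector, mixy as _mixy

            H = entropy_vector(self.alignment)
            candidates = []
            for i, j in candidate_pairs:
                i, j = (i, j) if i < j else (j, i)
                table = pair_state_table(self.alignment, i, j)
                if table.n_effective < 2:
                    logger.info("pair (%d,%d) skipped: uninformative", i, j)
                    continue
                candidates.append(
                    CandidatePair(i, j, H[i - 1], H[j - 1], _mixy(table))
                )

        mixy_sm = ScoreMatrix("MIxy")
        for c in candidates:
            mixy_sm.set(c.col_i, c.col_j, c.mixy)

        scores: dict[str, ScoreMatrix] = {}
        if "MIxy" in methods or "MIp" in methods:
            scores["MIxy"] = mixy_sm
        if "MIp" in methods:
            scores["MIp"] = mip(mixy_sm)
            try:
                scores["MIp_Z"] = zscores(scores["MIp"])
            except ValueError as exc:
                logger.warning("MIp Z-scores skipped: %s", exc)

        pec_result: Optional[PECResult] = None
        if "CPE" in methods:
            pec_result = pec_scan(
                self.alignment, self.phylogeny,
                [(c.col_i, c.col_j) for c in candidates],
                min_total_events=cfg.min_total_events,
            )
            scores["CPE"] = pec_result.cpe_scores

        nbest: dict[str, list[NBestResult]] = {}
        calls: dict[str, list[tuple[int, int]]] = {}
        for method in methods:
            if method not in scores or not len(scores[method]):
                continue
            nbest[method] = joint_nbest(scores[method], cfg.nbest_threshold)
            calls[method] = passed_pairs(nbest[method])

        merged: dict[tuple[int, int], str] = {}
        if "MIxy" in calls and "MIp" in calls:
            mi_union = merge_calls(calls["MIxy"], calls["MIp"],
                                   "MIxy", "MIp")
            calls["MI"] = sorted(mi_union)
        if "CPE" in calls:
            mi_calls = calls.get("MI", calls.get("MIxy", calls.get("MIp", [])))
            merged = merge_calls(calls["CPE"], mi_calls, "PEC", "MI")

        return CovariationResults(
            model=self, candidates=candidates, scores=scores,
            pec_result=pec_result, nbest=nbest, calls=calls, merged=merged,
        )


@dataclass
class CovariationResults:
    """Scores, calls and downstream analyses from a fitted model."""

    model: CovariationModel
    candidates: list[CandidatePair]
    scores: dict[str, ScoreMatrix]
    pec_result: Optional[PECResult]
    nbest: dict[str, list[NBestResult]]
    calls: dict[str, list[tuple[int, int]]]
    merged: dict[tuple[int, int], str]

    # -- derived stages ----------------------------------------------------

    def all_called_pairs(self) -> list[tuple[int, int]]:
        """Non-redundant union of calls across methods (PEC ∪ MI)."""
        if self.merged:
            return sorted(self.merged)
        out: set[tuple[int, int]] = set()
        for pairs in self.calls.values():
            out.update(pairs)
        return sorted(out)

    def extend_helices(
        self, nucleation: Optional[Iterable[tuple[int, int]]] = None
    ) -> HelixExtensionResult:
        nucleation = (list(nucleation) if nucleation is not None
                      else self.all_called_pairs())
        return helix_extend(
            self.model.alignment, nucleation,
            self.model.config.canonical_fraction,
        )

    def purity_scores(
        self, pairs: Optional[Iterable[tuple[int, int]]] = None
    ) -> list[PurityResult]:
        pairs = list(pairs) if pairs is not None else self.all_called_pairs()
        out = []
        for i, j in pairs:
            table = pair_state_table(self.model.alignment, i, j)
            if table.n_effective == 0:
                logger.info("pair (%d,%d): purity undefined, skipped", i, j)
                continue
            out.append(purity(table))
        return out

    def neighbor_effects(self) -> list[NeighborEffect]:
        if self.pec_result is None:
            raise ValueError("neighbor effects require a CPE fit")
        cfg = self.model.config
        return neighbor_effects(
            self.pec_result, self.all_called_pairs(),
            structure=self.model.structure,
            position_map=self.model.position_map,
            ratio_min=cfg.neighbor_ratio_min,
            cpe_min=cfg.cpe_min, events_min=cfg.events_min,
        )

    def ranked_calls(self, method: str) -> list[tuple[int, int]]:
        """Passed pairs of one method ranked by descending score."""
        sm = self.scores[method]
        return sorted(self.calls[method], key=lambda p: -sm.get(*p))

    def evaluate(self, method: Optional[str] = None) -> EvaluationReport:
        if self.model.structure is None or self.model.position_map is None:
            raise ValueError(
                "evaluation requires a reference structure and position map"
            )
        pairs = (self.ranked_calls(method) if method
                 else self.all_called_pairs())
        return evaluate_calls(pairs, self.model.position_map,
                              self.model.structure)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        aln = self.model.alignment
        lines = [
            "Covariation analysis summary",
            "============================",
            f"alignment:        {aln.n_sequences} sequences x "
            f"{aln.n_columns} columns",
            f"candidate pairs:  {len(self.candidates)} "
            f"(coarse filter: |dH| <= {self.model.config.entropy_tol}, "
            f"top {self.model.config.top_k})",
        ]
        if self.pec_result is not None:
            n_scored = len(self.pec_result.cpe_scores)
            n_excl = len(self.pec_result.excluded)
            lines.append(
                f"PEC:              {n_scored} pairs scored, "
                f"{n_excl} excluded (< {self.model.config.min_total_events} "
                "events or uninformative)"
            )
        for method in ("CPE", "MIxy", "MIp", "MI"):
            if method in self.calls:
                lines.append(
                    f"{method + '/JN-Best:':<18}{len(self.calls[method])} "
                    f"pairs called"
                )
        if self.merged:
            tags = pd.Series(list(self.merged.values())).value_counts()
            parts = ", ".join(f"{k}={v}" for k, v in tags.items())
            lines.append(f"merged calls:     {len(self.merged)} ({parts})")
        if self.model.structure is not None and self.model.position_map is not None:
            rep = self.evaluate()
            lines.append(
                f"vs. structure:    {rep.n_true_positive} TP, "
                f"{rep.n_false_positive} FP, {rep.n_unmappable} unmappable"
                + (f" (precision {rep.precision:.3f})"
                   if rep.precision is not None else "")
            )
        return "\n".join(lines)

    # -- export ------------------------------------------------------------

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """All result tables as DataFrames keyed by output name."""
        pm = self.model.position_map
        frames: dict[str, pd.DataFrame] = {}
        frames["candidates"] = pd.DataFrame(
            [{"col_i": c.col_i, "col_j": c.col_j, "H_i": c.entropy_i,
              "H_j": c.entropy_j, "mixy": c.mixy} for c in self.candidates]
        )
        for name, sm in self.scores.items():
            frames[f"scores_{name}"] = pd.DataFrame(sm.to_records(pm))
        if self.pec_result is not None:
            frames["pec_events"] = pd.DataFrame(self.pec_result.to_records(pm))
        call_rows = []
        for method, results in self.nbest.items():
            for r in results:
                call_rows.append({
                    "col_i": r.col_i, "col_j": r.col_j, "method": method,
                    "nbest_i": r.nbest_i, "nbest_j": r.nbest_j,
                    "mutual_best": r.mutual_best, "passed": r.passed,
                })
        frames["nbest"] = pd.DataFrame(call_rows)
        if self.merged:
            frames["merged_calls"] = pd.DataFrame(
                [{"col_i": i, "col_j": j, "provenance": tag}
                 for (i, j), tag in sorted(self.merged.items())]
            )
        return frames

    def write(self, outdir: str | Path) -> None:
        """Write every table as TSV with deterministic row order."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            if not frame.empty:
                frame = frame.sort_values(list(frame.columns[:2]))
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "config": self.model.config.to_dict(),
            "n_sequences": self.model.alignment.n_sequences,
            "n_columns": self.model.alignment.n_columns,
            "n_candidates": len(self.candidates),
            "calls": {m: len(p) for m, p in self.calls.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
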
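"""End-to-end orchestration: DE -> redundancy removal -> refinement ->
classification -> time-point categorisation -> subclustering.

Stages run on the DE subset only, in the order a post-assembly curation
study applies them.  Every stage's output is written as plain text under
the run directory, together with a run log echoing every parameter, so a
run is auditable and reproducible: the same config and seed produce
byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import quant
from .curation import (
    detect_frameshift,
    detect_intron_retention,
    greedy_cluster,
    merge_fragments,
    pairwise_identity,
)
from .dge import DEResult, call_de
from .homology import ContigClass, classify_contig
from .profiles import categorise_timepoints, sample_correlation, subcluster
from .synth import SimDesign, SyntheticDataset, simulate_dataset


@dataclass
class RunConfig:
    """Every knob of a pipeline run; echoed verbatim into the run log."""

    design: SimDesign = field(default_factory=SimDesign)
    lfc_min: float = 2.0
    fdr_max: float = 0.01
    identity_threshold: float = 0.95
    min_orf_aa: int = 33
    noncanonical_ratio: float = 1.5
    min_evalue: float = 1e-3
    min_identity: float = 0.35
    min_query_cov: float = 0.5
    prefilter: bool = True
    min_overlap: int = 20
    min_intron: int = 50
    max_junction: int = 10
    delta_min: float = 1.0
    cv_max: float = 0.5
    cut_fraction: float = 0.5
    linkage_method: str = "complete"
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    report: pd.DataFrame
    summary: dict
    de_result: DEResult
    categories: pd.DataFrame
    subclusters: pd.Series
    sample_corr: pd.DataFrame
    config: RunConfig


def _flag_contaminants(
    contigs: dict[str, str], decoys: dict[str, str], threshold: float
) -> set[str]:
    if not decoys:
        return set()
    flagged = set()
    for cid in sorted(contigs):
        for did in sorted(decoys):
            if pairwise_identity(contigs[cid], decoys[did]) >= threshold:
                flagged.add(cid)
                break
    return flagged


def _classify_all(
    contigs: dict[str, str],
    ds: SyntheticDataset,
    cfg: RunConfig,
) -> dict[str, ContigClass]:
    out = {}
    for cid in sorted(contigs):
        out[cid] = classify_contig(
            cid,
            contigs[cid],
            ds.ref_proteome,
            ds.comparator_proteomes,
            ds.prior_assembly or None,
            min_aa=cfg.min_orf_aa,
            min_evalue=cfg.min_evalue,
            min_identity=cfg.min_identity,
            min_query_cov=cfg.min_query_cov,
            prefilter=cfg.prefilter,
        )
    return out


def _subject_seq(ds: SyntheticDataset, klass: ContigClass) -> str | None:
    if klass.best_hit is None:
        return None
    db = (
        ds.ref_proteome
        if klass.best_hit_db == "reference"
        else ds.comparator_proteomes.get(klass.best_hit_db, {})
    )
    return db.get(klass.best_hit.subject_id)


def run_all(
    config: RunConfig,
    dataset: SyntheticDataset | None = None,
    counts: pd.DataFrame | None = None,
) -> RunResult:
    """Execute the full cascade; simulates the dataset unless one is given."""
    cfg = config
    if dataset is None or counts is None:
        dataset, counts = simulate_dataset(cfg.design)
    ds = dataset
    sheet = ds.sheet if ds.sheet is not None else cfg.design.sample_sheet()

    # --- stage 1: differential expression -------------------------------
    de = call_de(counts, sheet, lfc_min=cfg.lfc_min, fdr_max=cfg.fdr_max)
    de_ids = de.de_contigs()
    de_contigs = {cid: ds.contigs[cid] for cid in de_ids}

    # --- stage 2: contaminant flag + redundancy removal -----------------
    contaminants = _flag_contaminants(de_contigs, ds.decoy_db, cfg.identity_threshold)
    clean = {cid: s for cid, s in de_contigs.items() if cid not in contaminants}
    clusters = greedy_cluster(clean, cfg.identity_threshold)
    redundant = {
        m: rep
        for rep, members in clusters.clusters.items()
        for m in members
        if m != rep
    }
    reps = {rep: clean[rep] for rep in clusters.representatives}

    # --- stage 3: classification ----------------------------------------
    classes = _classify_all(reps, ds, cfg)

    # --- stage 4: assembly refinement -----------------------------------
    refinement: dict[str, list[str]] = {cid: [] for cid in reps}
    source_of: dict[str, str] = {cid: cid for cid in reps}  # final id -> DE-table id
    merged_counts: dict[str, list[str]] = {}

    # fragment merging among contigs hitting the same subject
    by_subject: dict[tuple[str, str], list[str]] = {}
    for cid, kl in classes.items():
        if kl.best_hit is not None:
            by_subject.setdefault((kl.best_hit_db, kl.best_hit.subject_id), []).append(cid)
    final = dict(reps)
    for key in sorted(by_subject):
        group = sorted(by_subject[key])
        if len(group) < 2:
            continue
        for i, a in enumerate(group):
            if a not in final:
                continue
            for b in group[i + 1 :]:
                if b not in final:
                    continue
                merged = merge_fragments(
                    final[a], final[b], cfg.min_overlap, cfg.identity_threshold
                )
                if merged is None:
                    continue
                mid = f"{a}+{b}"
                del final[a], final[b]
                final[mid] = merged
                source_of[mid] = a
                merged_counts[mid] = [a, b]
                refinement[mid] = refinement.pop(a) + refinement.pop(b) + [
                    f"fragment_pair:{a}|{b}"
                ]
                classes[mid] = classify_contig(
                    mid, merged, ds.ref_proteome, ds.comparator_proteomes,
                    ds.prior_assembly or None, min_aa=cfg.min_orf_aa,
                    min_evalue=cfg.min_evalue, min_identity=cfg.min_identity,
                    min_query_cov=cfg.min_query_cov, prefilter=cfg.prefilter,
                )
                break

    # intron retention + frameshift flags on the final sequences
    for cid in sorted(final):
        subject = _subject_seq(ds, classes[cid])
        if subject is None:
            continue
        flag = detect_intron_retention(cid, final[cid], subject, cfg.min_intron)
        if flag is not None:
            refinement[cid].append(f"{flag.kind}:{flag.evidence}")
            if flag.corrected:
                final[cid] = flag.corrected
        flag = detect_frameshift(cid, final[cid], subject, cfg.max_junction)
        if flag is not None:
            refinement[cid].append(f"{flag.kind}:{flag.evidence}")

    # --- stage 5: expression transforms ---------------------------------
    rows = {}
    for cid in final:
        src = merged_counts.get(cid)
        rows[cid] = counts.loc[src].sum(axis=0) if src else counts.loc[cid]
    final_counts = pd.DataFrame(rows).T.loc[sorted(final)]
    lengths = pd.Series({cid: len(s) for cid, s in final.items()})
    lib = (
        sheet.set_index("sample_id")["library_size"].reindex(final_counts.columns)
        if "library_size" in sheet.columns
        else None
    )
    fpkm = quant.fpkm(final_counts, lengths, lib)
    log2fpkm = np.log2(fpkm + 1.0)
    log2mc = quant.log2_median_center(fpkm)

    # --- stage 6: time-point categorisation -----------------------------
    cat_source = sorted({source_of[cid] for cid in final})
    cats_src = categorise_timepoints(
        de, log2fpkm.rename(index={cid: source_of[cid] for cid in final}),
        sheet, contigs=cat_source, delta_min=cfg.delta_min, cv_max=cfg.cv_max,
    )
    src_to_final = {source_of[cid]: cid for cid in final}
    cats = cats_src.table.rename(index=src_to_final)

    # --- stage 7: subclustering of categorisable contigs ----------------
    categorisable = [cid for cid in sorted(final) if not cats.loc[cid, "uncategorisable"]]
    if len(categorisable) >= 2:
        sc = subcluster(log2mc.loc[categorisable], cfg.cut_fraction, cfg.linkage_method)
        assignments = sc.assignments
    else:
        assignments = pd.Series(dtype=int, name="subcluster")
    corr, _ = sample_correlation(log2mc) if len(final) >= 2 else (pd.DataFrame(), None)

    # --- report ----------------------------------------------------------
    report_rows = []
    for cid in sorted(final):
        kl = classes[cid]
        report_rows.append(
            {
                "contig_id": cid,
                "de": True,
                "class": kl.label,
                "orf": kl.orf.fasta_id() if kl.orf else "",
                "refinement_flags": ";".join(refinement[cid]),
                "cat3": cats.loc[cid, "cat3"],
                "cat20": cats.loc[cid, "cat20"],
                "cat96": cats.loc[cid, "cat96"],
                "basis": cats.loc[cid, "basis"],
                "uncategorisable": bool(cats.loc[cid, "uncategorisable"]),
                "prior_assembly_support": (
                    "" if kl.prior_assembly_support is None else str(kl.prior_assembly_support)
                ),
                "subcluster": int(assignments.get(cid, 0)),
                "evidence": "; ".join(kl.evidence),
            }
        )
    report = pd.DataFrame(report_rows)

    summary = summarise(report)
    summary["n_de"] = len(de_ids)
    summary["n_contaminants"] = len(contaminants)
    summary["n_redundant_removed"] = len(redundant)
    summary["n_after_redundancy"] = len(reps)
    summary["n_final"] = len(final)
    summary["n_uncategorisable"] = int(report["uncategorisable"].sum())
    summary["n_categorisable"] = len(final) - summary["n_uncategorisable"]
    summary["n_subclusters"] = int(assignments.max()) if len(assignments) else 0
    summary["dispersion_estimate"] = de.dispersion

    result = RunResult(report, summary, de, cats, assignments, corr, cfg)
    if cfg.outdir:
        _write_outputs(result, final, counts, sheet, ds)
    return result


def summarise(report: pd.DataFrame) -> dict:
    """Cross-tabulate time point x direction x contig class (the final
    accounting of DE contigs by type and time of response)."""
    table: dict[str, dict[str, int]] = {}
    class_counts: dict[str, int] = {}
    for _, row in report.iterrows():
        if row.get("uncategorisable", False):
            continue
        class_counts[row["class"]] = class_counts.get(row["class"], 0) + 1
        for tp, col in ((3, "cat3"), (20, "cat20"), (96, "cat96")):
            direction = row[col]
            if direction == "ns":
                continue
            cell = table.setdefault(f"{tp}hps_{direction}", {})
            cell[row["class"]] = cell.get(row["class"], 0) + 1
    per_tp = {
        tp: sum(
            sum(cells.values())
            for key, cells in table.items()
            if key.startswith(f"{tp}hps_")
        )
        for tp in (3, 20, 96)
    }
    return {
        "timepoint_direction_class": table,
        "n_de_per_timepoint": per_tp,
        "class_counts": class_counts,
    }


def _write_outputs(
    result: RunResult,
    final: dict[str, str],
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    ds: SyntheticDataset,
) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    result.de_result.table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    result.categories.to_csv(out / "categories.tsv", sep="\t")
    result.subclusters.rename("subcluster").to_csv(out / "subclusters.tsv", sep="\t")
    if len(result.sample_corr):
        result.sample_corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    dio.write_fasta(dict(sorted(final.items())), out / "final_contigs.fasta")
    dio.write_counts(counts, out / "counts.tsv")
    dio.write_sample_sheet(sheet, out / "samples.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=1, sort_keys=True, default=str)
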
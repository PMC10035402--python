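"""End-to-end orchestration: simulate input bundles and run every stage.

``simulate_to_dir`` writes a synthetic input bundle in the same formats the
readers consume; ``run_all`` reads such a bundle (or real data laid out the
same way), then runs merge -> rescue -> classify -> subtype -> phylogeny ->
signatures -> summary in fixed order and writes one result bundle.  Reruns
with identical inputs are byte-identical: outputs carry the config hash and
seed, never timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as mio
from .clonality import (MergedVariant, RescueParams, classify_merged,
                        clonality_summary, merge_patient_variants)
from .cohort_stats import summarize_cohort
from .phylogeny import patient_tree
from .signatures import fits_to_frame, stratified_signatures, synthetic_catalog
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort
from .subtyping import (SubtypeThresholds, assign_subtype, cnv_altered_fraction,
                        msi_score, patient_evidence, subtype_frequencies)

logger = logging.getLogger(__name__)

BUNDLE_FILES = {
    "cohort": "cohort.tsv",
    "variants": "variants.tsv",
    "biopsies": "biopsies.tsv",
    "cnv": "cnv_segments.tsv",
    "msi": "msi_histograms.tsv",
    "ebv": "ebv_fractions.tsv",
    "panel_bed": "panel.bed",
    "panel_cds": "gene_cds.tsv",
    "catalog": "signature_catalog.synthetic.tsv",
    "truth": "truth.tsv",
    "config": "sim_config.yaml",
}


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclass_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def dataclass_to_dict(config: SimulationConfig) -> dict:
    import dataclasses

    def conv(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return {f.name: conv(getattr(config, f.name))
            for f in dataclasses.fields(config)}


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> SyntheticCohort:
    """Simulate a cohort and write the full input bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    mio.write_cohort_table(cohort.patients, outdir / BUNDLE_FILES["cohort"])
    all_calls = [c for pid in sorted(cohort.variant_calls)
                 for c in cohort.variant_calls[pid]]
    mio.write_variant_table(all_calls, outdir / BUNDLE_FILES["variants"])
    with (outdir / BUNDLE_FILES["biopsies"]).open("w") as fh:
        fh.write("patient_id\tbiopsy_id\n")
        for pid in sorted(cohort.biopsies):
            for bid in cohort.biopsies[pid]:
                fh.write(f"{pid}\t{bid}\n")
    mio.write_cnv_segments(
        [s for pid in sorted(cohort.cnv_segments) for s in cohort.cnv_segments[pid]],
        outdir / BUNDLE_FILES["cnv"])
    mio.write_msi_histograms(
        {pid: cohort.msi_loci[pid] for pid in sorted(cohort.msi_loci)},
        outdir / BUNDLE_FILES["msi"])
    mio.write_ebv_fractions(
        {pid: cohort.ebv_fractions[pid] for pid in sorted(cohort.ebv_fractions)},
        outdir / BUNDLE_FILES["ebv"])
    mio.write_panel(cohort.panel, outdir / BUNDLE_FILES["panel_bed"],
                    outdir / BUNDLE_FILES["panel_cds"])
    mio.write_signature_catalog(cohort.catalog, outdir / BUNDLE_FILES["catalog"])
    with (outdir / BUNDLE_FILES["truth"]).open("w") as fh:
        fh.write("patient_id\tchrom\tpos\tref\talt\ttrue_label\tstratum\tccf\n")
        for t in cohort.truth:
            ccf = ";".join(f"{b}={c:g}" for b, c in t.true_ccf)
            fh.write(f"{t.patient_id}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t"
                     f"{t.true_label}\t{t.stratum}\t{ccf}\n")
    with (outdir / BUNDLE_FILES["config"]).open("w") as fh:
        yaml.safe_dump(dataclass_to_dict(config), fh, sort_keys=True)
    return cohort


@dataclass
class RunResult:
    merged_by_patient: dict[str, list[MergedVariant]]
    subtype_calls: dict[str, str]
    summary: dict


def run_all(indir: str | Path, outdir: str | Path,
            rescue: RescueParams | None = None,
            thresholds: SubtypeThresholds | None = None,
            seed: int = 0) -> RunResult:
    """Run every stage on an input bundle and write the result bundle.

    ``rescue=None`` uses default rescue thresholds; pass
    ``RescueParams`` to change them.  Missing optional inputs (catalog) fall
    back to the synthetic default catalog.
    """
    indir, outdir = Path(indir), Path(outdir)
    for key in ("cohort", "variants", "biopsies"):
        if not (indir / BUNDLE_FILES[key]).exists():
            raise FileNotFoundError(f"input bundle lacks {BUNDLE_FILES[key]}")
    outdir.mkdir(parents=True, exist_ok=True)
    rescue = rescue if rescue is not None else RescueParams()
    thresholds = thresholds or SubtypeThresholds()

    patients = mio.read_cohort_table(indir / BUNDLE_FILES["cohort"])
    calls = mio.read_variant_table(indir / BUNDLE_FILES["variants"])
    biopsy_order: dict[str, list[str]] = defaultdict(list)
    for line in (indir / BUNDLE_FILES["biopsies"]).read_text().splitlines()[1:]:
        pid, bid = line.split("\t")
        biopsy_order[pid].append(bid)
    cat_path = indir / BUNDLE_FILES["catalog"]
    catalog = (mio.read_signature_catalog(cat_path) if cat_path.exists()
               else synthetic_catalog())
    panel = mio.read_panel(indir / BUNDLE_FILES["panel_bed"],
                           indir / BUNDLE_FILES["panel_cds"])
    segments = mio.read_cnv_segments(indir / BUNDLE_FILES["cnv"])
    msi_by_patient = mio.read_msi_histograms(indir / BUNDLE_FILES["msi"])
    ebv_by_patient = mio.read_ebv_fractions(indir / BUNDLE_FILES["ebv"])

    config_tag = "external"
    cfg_path = indir / BUNDLE_FILES["config"]
    if cfg_path.exists():
        config_tag = hashlib.sha256(cfg_path.read_bytes()).hexdigest()[:12]
    header = f"# mrith run: config={config_tag} seed={seed}\n"

    # --- clonality -------------------------------------------------------
    calls_by_patient: dict[str, list] = defaultdict(list)
    for c in calls:
        calls_by_patient[c.patient_id].append(c)
    merged_by_patient: dict[str, list[MergedVariant]] = {}
    for pid in sorted(biopsy_order):
        merged = merge_patient_variants(calls_by_patient.get(pid, []),
                                        biopsy_order[pid])
        merged_by_patient[pid] = classify_merged(merged, rescue=rescue)

    with (outdir / "clonality.tsv").open("w") as fh:
        fh.write(header)
        fh.write("patient_id\tchrom\tpos\tref\talt\tgene\teffect\t"
                 "presence\trescued\tclonality\n")
        for pid in sorted(merged_by_patient):
            for m in merged_by_patient[pid]:
                pres = "".join("1" if p else "0" for p in m.presence)
                resc = "".join("1" if r else "0" for r in m.rescued)
                fh.write(f"{pid}\t{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t"
                         f"{m.gene or 'NA'}\t{m.effect or 'NA'}\t"
                         f"{pres}\t{resc}\t{m.clonality}\n")

    # --- subtype ---------------------------------------------------------
    segs_by_patient: dict[str, list] = defaultdict(list)
    biopsy_owner = {b: pid for pid, bids in biopsy_order.items() for b in bids}
    for s in segments:
        pid = biopsy_owner.get(s.biopsy_id)
        if pid is not None:
            segs_by_patient[pid].append(s)
    subtype_calls: dict[str, str] = {}
    with (outdir / "subtype.tsv").open("w") as fh:
        fh.write(header)
        fh.write("patient_id\tsubtype\tebv_read_fraction\tmsi_score\t"
                 "cnv_altered_fraction\n")
        for pid in sorted(biopsy_order):
            score = msi_score(msi_by_patient.get(pid, []))
            per_biopsy_altered = [
                cnv_altered_fraction(
                    [s for s in segs_by_patient.get(pid, []) if s.biopsy_id == bid],
                    panel)
                for bid in biopsy_order[pid]
            ]
            ev = patient_evidence(ebv_by_patient.get(pid, {}), score,
                                  per_biopsy_altered)
            call = assign_subtype(ev, patient_id=pid, thresholds=thresholds)
            subtype_calls[pid] = call.subtype
            fh.write(f"{pid}\t{call.subtype}\t{ev.ebv_read_fraction:.6g}\t"
                     f"{ev.msi_score:.6g}\t{ev.cnv_altered_fraction:.6g}\n")

    # --- phylogeny -------------------------------------------------------
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    with (outdir / "pattern_conflicts.tsv").open("w") as fh:
        fh.write(header)
        fh.write("patient_id\tdropped_mask\tmutation_count\n")
        for pid in sorted(merged_by_patient):
            classified = [m for m in merged_by_patient[pid]
                          if m.clonality != "NONE"]
            tree, dropped = patient_tree(classified, biopsy_order[pid])
            mio.write_newick(tree, trees_dir / f"{pid}.nwk")
            for p in dropped:
                fh.write(f"{pid}\t{p.mask:b}\t{p.mutation_count}\n")

    # --- signatures ------------------------------------------------------
    all_merged = [m for pid in sorted(merged_by_patient)
                  for m in merged_by_patient[pid]]
    fits = stratified_signatures(all_merged, catalog, group_of=subtype_calls)
    frame = fits_to_frame(fits)
    with (outdir / "signatures.tsv").open("w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    # --- cohort summary --------------------------------------------------
    summary = summarize_cohort(patients)
    clon = clonality_summary(
        all_merged, {p.patient_id: subtype_calls.get(p.patient_id)
                     for p in patients})
    report = {
        "config": config_tag,
        "seed": seed,
        "n_patients": summary.n_patients,
        "percent_male": summary.percent_male,
        "mean_age": round(summary.mean_age, 1),
        "percent_advanced_stage": summary.percent_advanced_stage,
        "subtype_percents_assigned": subtype_frequencies(subtype_calls),
        "clonality_counts": clon.counts,
        "clonality_percents": clon.percents,
        "clonality_mean_per_patient": {
            k: round(v, 2) for k, v in clon.mean_per_patient.items()},
    }
    with (outdir / "summary.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(merged_by_patient=merged_by_patient,
                     subtype_calls=subtype_calls, summary=report)
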
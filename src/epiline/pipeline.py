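"""End-to-end orchestration of the synthetic epiallele analysis.

Stages communicate through conventionally named files in the run's output
directory, so each stage can also be invoked on its own (via the CLI) as
long as its inputs exist.  Outputs carry a provenance header (tool
version, config hash, stage seed) and contain no timestamps: re-running
the same config yields byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import climassoc, inherit, io, methstat, synthgen, tedate, tedetect
from .config import STAGES, ConfigError, RunConfig

__all__ = ["run", "run_stage"]

log = logging.getLogger("epiline")


def _header(config: RunConfig, stage: str) -> list[str]:
    return io.provenance_lines(stage, config.stage_seed(stage), config.config_hash(), __version__)


def _truth_path(outdir: Path) -> Path:
    return outdir / "truth.tsv"


def _read_truth(outdir: Path) -> dict[str, str]:
    frame = io.read_tsv(_truth_path(outdir))
    return dict(zip(frame["key"], frame["value"].astype(str)))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    seed = config.stage_seed("simulate")
    g = config["genome"]
    te_cfg = config["te"]
    ins_cfg = config["insertion"]

    genome = synthgen.make_reference(seed, {g["chrom"]: int(g["length"])}, g["gc_fraction"])
    te_family = synthgen.make_reference(seed + 1, {"te": int(te_cfg["length"])}, g["gc_fraction"])
    te_seq = te_family.sequences["te"]
    insertion = synthgen.PlantedInsertion(
        chrom=g["chrom"],
        point=int(ins_cfg["point"]),
        te_sequence=te_seq,
        inverted=bool(te_cfg["inverted"]),
        truncation=int(te_cfg["truncation"]),
        tsd_length=int(ins_cfg["tsd_length"]),
        name="NMR19_insertion",
    )
    carrier = synthgen.plant_insertion(genome, insertion)
    io.write_fasta(outdir / "reference.fa", genome.sequences)
    io.write_fasta(outdir / "carrier.fa", carrier.sequences)
    io.write_fasta(
        outdir / "te.fa",
        {"NMR19_family": te_seq, "NMR19_element_inserted": insertion.inserted_sequence},
    )

    r = config["reads"]
    pairs = synthgen.simulate_read_pairs(
        carrier,
        read_len=int(r["read_len"]),
        insert_mean=r["insert_mean"],
        insert_sd=r["insert_sd"],
        coverage=r["coverage"],
        error_rate=r["error_rate"],
        seed=seed + 2,
    )
    io.write_fastq_pairs(outdir / "reads", pairs)

    te_ann = carrier.annotations[-1]
    m = config["methylation"]
    region = (te_ann.chrom, te_ann.start, te_ann.end)
    meth = synthgen.simulate_bisulfite_calls(
        carrier, [(*region, "methylated")], m["depth_mean"], m["conversion_error"], seed + 3
    )
    unmeth = synthgen.simulate_bisulfite_calls(
        carrier, [(*region, "unmethylated")], m["depth_mean"], m["conversion_error"], seed + 4
    )
    io.write_cytosine_tsv(outdir / "cytosine_methylated.tsv", meth, _header(config, "simulate"))
    io.write_cytosine_tsv(outdir / "cytosine_unmethylated.tsv", unmeth, _header(config, "simulate"))

    c = config["cross"]
    marker_cm = tuple(i * float(c["marker_spacing_cm"]) for i in range(int(c["n_markers"])))
    cross_cfg = synthgen.CrossConfig(
        marker_cm=marker_cm,
        epi_locus_cm=float(c["epi_locus_cm"]),
        epsilon=float(c["epsilon"]),
        seed=seed + 5,
    )
    population = synthgen.simulate_cross(cross_cfg, "F2", int(c["n_f2"]))
    frame = synthgen.simulate_phenotypes(population, seed=seed + 6)
    io.write_tsv(outdir / "population.tsv", frame, _header(config, "simulate"))
    markers = pd.DataFrame(
        {"marker": cross_cfg.marker_names, "position_cm": cross_cfg.marker_cm}
    )
    io.write_tsv(outdir / "markers.tsv", markers, _header(config, "simulate"))

    d = config["dating"]
    evo = synthgen.EvolutionConfig(
        length=int(d["length"]),
        n_tips=int(d["n_tips"]),
        age_years=float(d["age_years"]),
        rate=float(d["rate"]),
        seed=seed + 7,
    )
    aligned = synthgen.evolve_star(evo)
    io.write_fasta(outdir / "nmr19_alignment.fa", dict(zip(aligned.names, aligned.sequences)))
    t_lo, t_hi = (float(x) for x in d["t_div_range"])
    orth = synthgen.evolve_star(
        synthgen.EvolutionConfig(
            length=int(d["length"]),
            n_tips=2,
            age_years=0.5 * (t_lo + t_hi),
            rate=float(d["rate"]),
            seed=seed + 8,
        )
    )
    io.write_fasta(outdir / "ortholog_pair.fa", dict(zip(["A_thaliana", "A_lyrata"], orth.sequences)))

    cl = config["climate"]
    climate = synthgen.simulate_climate_table(
        int(cl["n_accessions"]),
        tuple(cl["group_proportions"]),
        float(cl["bio9_effect"]),
        seed + 9,
    )
    io.write_tsv(outdir / "climate.tsv", climate, _header(config, "simulate"))

    truth = pd.DataFrame(
        {
            "key": [
                "chrom", "insertion_point", "te_start", "te_end", "tsd_length",
                "orientation", "age_years", "rate", "epi_locus_cm",
            ],
            "value": [
                te_ann.chrom, insertion.point, te_ann.start, te_ann.end,
                insertion.tsd_length, "inverted" if insertion.inverted else "same",
                evo.age_years, evo.rate, c["epi_locus_cm"],
            ],
        }
    )
    io.write_tsv(_truth_path(outdir), truth, _header(config, "simulate"))
    log.info("simulate: genome %s bp, %d read pairs, F2 n=%d", g["length"], len(pairs), c["n_f2"])
    return {"read_pairs": len(pairs), "f2_size": int(c["n_f2"])}


def stage_detect_te(config: RunConfig, outdir: Path) -> dict:
    genome = synthgen.GenomeModel(io.read_fasta(outdir / "reference.fa"))
    carrier = synthgen.GenomeModel(io.read_fasta(outdir / "carrier.fa"))
    te = io.read_fasta(outdir / "te.fa")
    pairs = io.read_fastq_pairs(outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    det = config["detection"]
    r = config["reads"]
    alignments = tedetect.naive_map(pairs, genome, {"NMR19_family": te["NMR19_family"]}, k=int(det["k"]))
    calls, candidates = tedetect.call_insertions(
        alignments,
        {"NMR19_family"},
        insert_mean=r["insert_mean"],
        insert_sd=r["insert_sd"],
        min_support=int(det["min_support"]),
    )
    for call in calls:
        tsd_len, tsd_seq = tedetect.tsd_from_genomes(
            genome, carrier, call, te["NMR19_element_inserted"], max_tsd=int(det["max_tsd"])
        )
        call.tsd_length, call.tsd_sequence = tsd_len, tsd_seq
    io.write_bedlike(outdir / "insertion_calls.tsv", calls, _header(config, "detect-te"))
    log.info("detect-te: %d calls, %d candidates", len(calls), len(candidates))
    return {
        "n_calls": len(calls),
        "n_candidates": len(candidates),
        "calls": [vars(c) for c in calls],
    }


def stage_methylation(config: RunConfig, outdir: Path) -> dict:
    truth = _read_truth(outdir)
    region = (truth["chrom"], int(truth["te_start"]), int(truth["te_end"]))
    meth = io.read_cytosine_tsv(outdir / "cytosine_methylated.tsv")
    unmeth = io.read_cytosine_tsv(outdir / "cytosine_unmethylated.tsv")
    thr = float(config["methylation"]["meth_threshold"])
    rows = []
    for sample, records in (("methylated_accession", meth), ("unmethylated_accession", unmeth)):
        lv = methstat.weighted_level(records, region)
        category = methstat.classify_accession(True, False, lv.levels["CG"], None, thr)
        rows.append(
            {
                "sample": sample,
                "level_total": lv.levels["total"],
                "level_CG": lv.levels["CG"],
                "level_CHG": lv.levels["CHG"],
                "level_CHH": lv.levels["CHH"],
                "category": category,
            }
        )
    p_chh = methstat.fisher_region_compare(meth, unmeth, region, "CHH")
    report = pd.DataFrame(rows)
    io.write_tsv(outdir / "methylation_report.tsv", report, _header(config, "methylation"))
    log.info("methylation: CHH Fisher p=%.3g", p_chh)
    return {"samples": rows, "fisher_chh_p": p_chh}


def stage_segregate(config: RunConfig, outdir: Path) -> dict:
    frame = io.read_tsv(outdir / "population.tsv")
    methylated = int((frame["epi_genotype"] != "uu").sum())
    unmethylated = int((frame["epi_genotype"] == "uu").sum())
    res = inherit.segregation_test((methylated, unmethylated), (3, 1))
    out = pd.DataFrame(
        {
            "phenotype": ["methylated_band", "unmethylated_only"],
            "observed": [methylated, unmethylated],
            "expected_ratio": [3, 1],
            "chi2": [res.chi2] * 2,
            "p_value": [res.p_value] * 2,
        }
    )
    io.write_tsv(outdir / "segregation.tsv", out, _header(config, "segregate"))
    log.info("segregate: %d:%d, chi2=%.3f p=%.3f", methylated, unmethylated, res.chi2, res.p_value)
    return {
        "observed": [methylated, unmethylated],
        "ratio": methylated / max(unmethylated, 1),
        "chi2": res.chi2,
        "p_value": res.p_value,
    }


def stage_map_locus(config: RunConfig, outdir: Path) -> dict:
    frame = io.read_tsv(outdir / "population.tsv")
    markers = io.read_tsv(outdir / "markers.tsv")
    positions = dict(zip(markers["marker"], markers["position_cm"]))
    table = inherit.linkage_table_from_frame(frame, positions)
    interval = inherit.map_locus(table)
    io.write_tsv(outdir / "linkage.tsv", table, _header(config, "map-locus"))
    result = {
        "best_marker": interval.best_marker,
        "best_position_cm": interval.best_position,
        "interval_cm": [interval.lo_position, interval.hi_position],
        "flag": interval.flagged,
        "true_epi_locus_cm": float(_read_truth(outdir)["epi_locus_cm"]),
    }
    (outdir / "locus_interval.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    log.info("map-locus: best=%s interval=%s", interval.best_marker, result["interval_cm"])
    return result


def stage_cosegregate(config: RunConfig, outdir: Path) -> dict:
    frame = io.read_tsv(outdir / "population.tsv")
    n = int(config["cross"]["n_coseg"])
    summary = inherit.cosegregation_summary(frame.head(n))
    io.write_tsv(outdir / "cosegregation.tsv", summary, _header(config, "cosegregate"))
    return {"variables": summary.to_dict("records")}


def stage_date_insertion(config: RunConfig, outdir: Path) -> dict:
    seqs = io.read_fasta(outdir / "nmr19_alignment.fa")
    aligned = tedate.AlignedSet(list(seqs), list(seqs.values()))
    orth = io.read_fasta(outdir / "ortholog_pair.fa")
    d = config["dating"]
    t_lo, t_hi = (float(x) for x in d["t_div_range"])
    result = tedate.date_insertion(aligned, tuple(orth.values()), (t_lo, t_hi))
    payload = {
        "rate_per_site_per_year": result.rate,
        "mean_pairwise_distance": result.mean_pairwise,
        "mean_to_ancestor": result.mean_to_ancestor,
        "t_star_years": result.t_star,
        "t_mrca_years": result.t_mrca,
        "age_range_years": list(result.age_range),
        "t_div_used_years": result.t_div_used,
        "t_star_sensitivity_years": list(result.t_star_range),
        "t_mrca_sensitivity_years": list(result.t_mrca_range),
        "notes": result.notes,
    }
    (outdir / "dating.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info(
        "date-insertion: T_star=%.3g y, T_mrca=%.3g y (rate %.3g)",
        result.t_star, result.t_mrca, result.rate,
    )
    return payload


def stage_climate(config: RunConfig, outdir: Path) -> dict:
    table = io.read_tsv(outdir / "climate.tsv")
    grouped, counts = climassoc.assign_groups(table)
    results, summary = climassoc.climate_scan(grouped, alpha=float(config["climate"]["alpha"]))
    shifts = climassoc.epoch_shift_tests(grouped, "bio9")
    io.write_tsv(outdir / "climate_associations.tsv", results, _header(config, "climate"))
    io.write_tsv(outdir / "climate_epoch_shifts.tsv", shifts, _header(config, "climate"))
    payload = {"group_counts": counts, "summary": summary}
    (outdir / "climate_summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info("climate: groups %s; associated present=%d lig=%d",
             counts, summary["present"]["n_associated"], summary["lig"]["n_associated"])
    return payload


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "detect-te": stage_detect_te,
    "methylation": stage_methylation,
    "segregate": stage_segregate,
    "map-locus": stage_map_locus,
    "cosegregate": stage_cosegregate,
    "date-insertion": stage_date_insertion,
    "climate": stage_climate,
}


def run_stage(name: str, config: RunConfig, outdir: Path | None = None) -> dict:
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown field 'stages': unrecognised stage {name!r}")
    outdir = Path(outdir) if outdir is not None else config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[name](config, outdir)


def run(config: RunConfig, outdir: Path | None = None) -> dict:
    """Execute the configured stages in dependency order; write a run report."""
    outdir = Path(outdir) if outdir is not None else config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    selected = [s for s in STAGES if s in config["stages"]]
    report: dict[str, dict] = {"config_hash": config.config_hash(), "seed": config.seed}
    for stage in selected:
        log.info("running stage %s", stage)
        report[stage] = _STAGE_FUNCS[stage](config, outdir)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
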
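"""End-to-end orchestration: fixture generation, configured runs,
and the run report.

A run executes preprocess -> map -> known annotation -> novel
discovery -> (optional) target scan -> (optional) chip analysis from a
single config; identical config + seed gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import annotate, chip, hairpin, mapping, preprocess, simulate, targets
from ._seq import canonical, revcomp

log = logging.getLogger("grainmir")


@dataclass
class RunConfig:
    genome: str = "genome.fa"
    reads: str = "reads.fq"
    contaminants: str = "contaminants.fa"
    catalog_mature: str = "catalog_mature.fa"
    catalog_precursor: str = "catalog_precursor.fa"
    catalog_links: str = "catalog_links.tsv"
    transcripts: str | None = "transcripts.fa"
    chip_signals: str | None = "chip_signals.tsv"
    chip_background: str | None = "chip_background.tsv"
    adapter: str | None = None
    min_len: int = 18
    max_len: int = 26
    max_hits: int = 20
    max_mismatches: int = 6
    max_bulges: int = 3
    max_target_score: float = 5.0
    detection_floor: float = 32.0
    min_abundance: float = 100.0
    fold_cutoff: float = 2.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


FIXTURE_SCALES = {
    # hairpins, known hairpins, chrom_len, n_reads, chip probes
    "tiny": dict(n_novel=3, n_known=1, chrom_len=10_000, n_reads=3_000,
                 n_probes=12),
    "demo": dict(n_novel=5, n_known=2, chrom_len=20_000, n_reads=20_000,
                 n_probes=40),
}

#: Chip expression programs planted in fixtures (multiplier triplets).
_CHIP_PATTERNS = [
    ("up_late", (1.0, 1.0, 5.53), 200.0),
    ("up_early", (1.0, 3.27, 3.6), 350.0),
    ("down_early", (1.0, 0.27, 0.15), 250.0),
    ("down_late", (1.0, 0.9, 0.14), 770.0),
    ("flat", (1.0, 1.0, 1.0), 400.0),
    ("low", (1.0, 1.2, 1.4), 20.0),
]


def make_fixture(outdir, seed: int = 0, scale: str = "tiny",
                 force: bool = False) -> RunConfig:
    """Write a complete synthetic input set with ground truth.

    The directory gets a genome with planted hairpins, a FASTQ read
    population, contaminant and known-miRNA catalogs, transcripts with
    planted target sites, chip signal tables, truth tables and a
    ready-to-run config.yaml.
    """
    params = FIXTURE_SCALES[scale]
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = simulate._substream(seed, 10)

    n_total = params["n_novel"] + params["n_known"]
    spacing = params["chrom_len"] // (n_total + 1)
    hairpins = []
    for i in range(n_total):
        kind = "novel" if i < params["n_novel"] else "known"
        hairpins.append(simulate.random_hairpin(
            rng, f"{kind}_{i + 1}", "chr1", spacing * (i + 1),
            strand="+" if i % 2 == 0 else "-",
            mature_len=21 if i % 2 == 0 else 24,
            loop_len=8 + i, mature_arm="5p" if i % 3 else "3p"))
    genome, truth = simulate.generate_genome(
        1, params["chrom_len"], hairpins, seed=seed)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    truth["kind"] = ["novel"] * params["n_novel"] + ["known"] * params["n_known"]
    truth.to_csv(outdir / "truth_hairpins.tsv", sep="\t", index=False)

    contaminants = simulate.default_contaminants(seed=seed)
    with open(outdir / "contaminants.fa", "w") as fh:
        for name, seq in sorted(contaminants.items()):
            fh.write(f">{name}\n{seq}\n")

    # known catalog: mature + star records for the 'known' hairpins
    with open(outdir / "catalog_mature.fa", "w") as mfa, \
            open(outdir / "catalog_precursor.fa", "w") as pfa, \
            open(outdir / "catalog_links.tsv", "w") as links:
        links.write("name\tprecursor_id\toffset\tarm\n")
        for i, hp in enumerate(h for h in hairpins
                               if h.locus_id.startswith("known")):
            pre = hp.precursor_dna
            name = f"osa-miR90{i + 1}"
            pfa.write(f">MIR90{i + 1}\n{pre}\n")
            mfa.write(f">{name}\n{canonical(hp.mature_seq)}\n")
            links.write(f"{name}\tMIR90{i + 1}\t{hp.mature_offset}"
                        f"\t{hp.mature_arm}\n")
            star = canonical(hp.star_seq)
            star_off = pre.find(star)
            star_arm = "3p" if hp.mature_arm == "5p" else "5p"
            mfa.write(f">{name}*\n{star}\n")
            links.write(f"{name}*\tMIR90{i + 1}\t{star_off}\t{star_arm}\n")

    profile = simulate.ReadLengthProfile(simulate.DEFAULT_LENGTH_PROFILE)
    reads = simulate.simulate_reads(
        hairpins, profile, params["n_reads"],
        mature_fraction=0.10, star_fraction=0.02,
        contaminant_fraction=0.10, contaminants=contaminants, seed=seed)
    simulate.write_fastq(reads, outdir / "reads.fq")
    pd.DataFrame([{"category": r.category, "locus_id": r.locus_id or "",
                   "sequence": r.sequence} for r in reads]
                 ).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)

    # transcripts with one perfect target site per novel mature sequence
    with open(outdir / "transcripts.fa", "w") as fh, \
            open(outdir / "truth_targets.tsv", "w") as tt:
        tt.write("transcript_id\tlocus_id\tsite_start\n")
        for i, hp in enumerate(h for h in hairpins
                               if h.locus_id.startswith("novel")):
            mature = canonical(hp.mature_seq)
            body = simulate._random_seq(rng, 500)
            pos = 100 + 50 * i
            seq = body[:pos] + revcomp(mature) + body[pos:]
            fh.write(f">tx{i + 1}\n{seq}\n")
            tt.write(f"tx{i + 1}\t{hp.locus_id}\t{pos}\n")

    probes = []
    for j in range(params["n_probes"]):
        name, mult, base = _CHIP_PATTERNS[j % len(_CHIP_PATTERNS)]
        probes.append(simulate.ChipTruth(
            f"probe_{j + 1:03d}_{name}", base, mult, noise_cv=0.08))
    signals, background = simulate.simulate_chip(
        probes, replicates=3, background_mean=30.0, background_sd=4.0,
        seed=seed)
    signals.to_csv(outdir / "chip_signals.tsv", sep="\t", index=False)
    background.to_csv(outdir / "chip_background.tsv", sep="\t", index=False)
    pd.DataFrame([{"probe_id": p.probe_id, "base_signal": p.base_signal,
                   "mult_G1": p.stage_multipliers[0],
                   "mult_G2": p.stage_multipliers[1],
                   "mult_G3": p.stage_multipliers[2],
                   "noise_cv": p.noise_cv} for p in probes]
                 ).to_csv(outdir / "truth_chip.tsv", sep="\t", index=False)

    config = RunConfig(seed=seed)
    config.to_yaml(outdir / "config.yaml")
    return config


def _load_genome(path) -> dict[str, str]:
    return {rec.id: canonical(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def run(config: RunConfig, workdir, outdir=None) -> dict:
    """Execute the pipeline on a fixture/input directory; returns (and
    writes) the run report."""
    workdir = Path(workdir)
    outdir = Path(outdir) if outdir else workdir / "out"
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.digest(), "seed": config.seed,
                    "stages": {}}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    # --- preprocess
    t0 = stage("preprocess")
    raw = preprocess.read_sequences(workdir / config.reads)
    contaminants = {rec.id: canonical(str(rec.seq)) for rec in
                    SeqIO.parse(str(workdir / config.contaminants), "fasta")}
    collapsed, prep_report = preprocess.preprocess(
        raw, adapter=config.adapter, min_len=config.min_len,
        max_len=config.max_len, contaminants=contaminants)
    preprocess.write_collapsed_fasta(collapsed, outdir / "collapsed.fa")
    report["stages"]["preprocess"] = prep_report.to_dict()
    log.info("preprocess done in %.1fs", time.time() - t0)

    # --- map
    t0 = stage("map")
    genome = _load_genome(workdir / config.genome)
    index = mapping.build_index(genome)
    hit_map, discarded = mapping.map_reads(collapsed, index, config.max_hits)
    summary = mapping.summarize(collapsed, hit_map)
    mapping.write_bed(collapsed, hit_map, outdir / "hits.bed")
    report["stages"]["mapping"] = {
        "unique_sequences": summary.unique_sequences,
        "aligned_sequences": summary.aligned_sequences,
        "percent_aligned": summary.percent_aligned,
        "multi_mapped_discarded": len(discarded),
    }
    log.info("mapping done in %.1fs", time.time() - t0)

    # --- known annotation
    t0 = stage("annotate")
    catalog = annotate.load_catalog(workdir / config.catalog_mature,
                                    workdir / config.catalog_precursor,
                                    workdir / config.catalog_links)
    matches = annotate.annotate_reads(collapsed, catalog)
    fam = annotate.family_table(matches, collapsed)
    fam.to_csv(outdir / "known_families.tsv", sep="\t", index=False)
    report["stages"]["known"] = {
        "matched_sequences": len(matches),
        "matched_reads": int(sum(r.count for r in collapsed
                                 if r.sequence in matches)),
        "families": sorted(fam["family"].unique()) if len(fam) else [],
    }
    log.info("annotation done in %.1fs", time.time() - t0)

    # --- novel discovery
    t0 = stage("discover")
    candidates = hairpin.discover(
        collapsed, hit_map, genome, known_sequences=set(matches),
        max_mismatches=config.max_mismatches, max_bulges=config.max_bulges)
    hairpin.write_candidates(candidates, outdir / "novel_candidates.tsv",
                             outdir / "novel_structures.txt")
    report["stages"]["discovery"] = {
        "candidates": len(candidates),
        "loci": [f"{c.chrom}:{c.start}-{c.end}({c.strand})"
                 for c in candidates],
    }
    log.info("discovery done in %.1fs", time.time() - t0)

    # --- target scan (optional)
    if config.transcripts and (workdir / config.transcripts).exists():
        t0 = stage("targets")
        transcripts = {rec.id: canonical(str(rec.seq)) for rec in
                       SeqIO.parse(str(workdir / config.transcripts), "fasta")}
        mirnas = {f"cand_{i + 1}": c.mature_seq
                  for i, c in enumerate(candidates)}
        aligns = targets.scan_many(mirnas, transcripts,
                                   config.max_target_score)
        targets.write_targets(aligns, outdir / "target_sites.tsv")
        report["stages"]["targets"] = {
            "sites": len(aligns),
            "perfect_sites": sum(1 for a in aligns if a.score == 0),
        }
        log.info("target scan done in %.1fs", time.time() - t0)
    else:
        report["stages"]["targets"] = "skipped"

    # --- chip analysis (optional)
    if (config.chip_signals and (workdir / config.chip_signals).exists()
            and config.chip_background
            and (workdir / config.chip_background).exists()):
        t0 = stage("chip")
        signals = pd.read_csv(workdir / config.chip_signals, sep="\t")
        background = pd.read_csv(workdir / config.chip_background, sep="\t")
        norm = chip.normalize(signals, background)
        calls = chip.detection_table(norm, background)
        de = chip.de_table(norm, config.min_abundance, config.fold_cutoff)
        calls.to_csv(outdir / "detection_calls.tsv", sep="\t", index=False)
        de.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        venn = chip.stage_overlap(calls)
        with open(outdir / "stage_overlap.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
        chip.log2_matrix(norm).to_csv(outdir / "log2_matrix.tsv", sep="\t")
        report["stages"]["chip"] = {
            "probes": int(de.shape[0]),
            "detected_per_stage": {
                s: int(calls[(calls["stage"] == s) &
                             calls["detected"]].shape[0])
                for s in chip.STAGES},
            "regulation_counts": de["regulation"].value_counts().to_dict(),
            "venn": venn,
        }
        log.info("chip analysis done in %.1fs", time.time() - t0)
    else:
        report["stages"]["chip"] = "skipped"

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
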
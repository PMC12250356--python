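"""End-to-end pipeline driver: simulation -> catalog -> abundance -> haplotypes -> slm.

A run is described by a single plain-text config (YAML key-value), which is
echoed into the output directory for provenance. Every output file is
listed in a JSON manifest with its SHA-256 content hash, so two runs with
the same config and seed can be compared by hash equality. All randomness
flows from the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import catalog as cat
from . import haplotypes as hap
from . import io as sio
from . import slm as slm_mod
from . import synthetic as syn

DEFAULT_STAGES = ["simulate", "catalog", "abundance", "haplotypes", "slm"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _family_specs(config: dict) -> list[syn.SatFamilySpec]:
    fams = config.get("families")
    if not fams:
        raise StageError("simulate stage needs a 'families' list in the config")
    return [syn.SatFamilySpec(**fam) for fam in fams]


def _library_sex(label: str) -> str:
    low = label.lower()
    if low.endswith("female") or low.endswith("_f"):
        return "F"
    if low.endswith("male") or low.endswith("_m"):
        return "M"
    raise StageError(f"cannot infer sex from library label {label!r}")


def _default_groups(libraries: list[str]) -> dict[str, str]:
    return {lib: lib for lib in libraries}


def run_pipeline(
    config: dict | str | os.PathLike,
    out_dir: str | os.PathLike | None = None,
    state: dict | None = None,
) -> dict:
    """Execute the configured stages in order and return the run manifest.

    ``state`` (optional) receives the in-memory objects each stage
    produces (catalog, mapping results, haplotype graph, SLM result, ...),
    which is convenient for programmatic use.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "sexsatkit_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", DEFAULT_STAGES)
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise StageError(f"unknown stages: {sorted(unknown)}")

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    manifest: dict = {"seed": seed, "stages": list(stages), "outputs": {}}
    if state is None:
        state = {}

    def record(stage: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[path.name] = _sha256(path)

    for stage in stages:
        try:
            if stage == "simulate":
                _stage_simulate(config, seed, out, state, record)
            elif stage == "catalog":
                _stage_catalog(config, out, state, record)
            elif stage == "abundance":
                _stage_abundance(config, seed, out, state, record)
            elif stage == "haplotypes":
                _stage_haplotypes(config, seed, out, state, record)
            elif stage == "slm":
                _stage_slm(config, out, state, record)
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    sio.write_json(out / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config, seed, out, state, record) -> None:
    reads_cfg = config.get("reads", {})
    specs = _family_specs(config)
    reads, truth = syn.simulate_libraries(
        specs,
        read_length=int(reads_cfg.get("read_length", 150)),
        n_reads_per_library=int(reads_cfg.get("n_reads_per_library", 2000)),
        seed=seed,
        genome_size=int(reads_cfg.get("genome_size", 100_000)),
    )
    for lib, lib_reads in reads.items():
        path = out / f"{lib}.fastq"
        sio.write_fastq(path, lib_reads, prefix=lib)
        record("simulate", path)
    prefix = config.get("catalog_prefix", "Sim")
    ranked = cat.name_catalog(
        [
            (t.consensus, spec.array_copies_per_genome * spec.rul)
            for spec, t in zip(specs, truth.sat_families)
        ],
        prefix=prefix,
    )
    state["catalog"] = ranked
    state["sat_names"] = {
        t.family_id: rec.name
        for t in truth.sat_families
        for rec in ranked
        if rec.consensus == t.consensus
    }
    path = out / "catalog.fasta"
    sio.write_fasta(path, [(r.name, r.consensus) for r in ranked])
    record("simulate", path)

    geno_cfg = config.get("genotypes")
    if geno_cfg:
        gspec = syn.GenotypeSimSpec(**{**geno_cfg, "seed": seed})
        matrix, sexes, gtruth = syn.simulate_genotypes(gspec)
        truth.slm_xy_loci = gtruth.slm_xy_loci
        truth.slm_zw_loci = gtruth.slm_zw_loci
        truth.slm_xy_indices = gtruth.slm_xy_indices
        truth.slm_zw_indices = gtruth.slm_zw_indices
        sio.write_genotype_csv(out / "genotypes.csv", matrix)
        sio.write_sex_map(out / "sexmap.csv", sexes)
        record("simulate", out / "genotypes.csv")
        record("simulate", out / "sexmap.csv")
        state["genotypes"] = matrix
        state["sexes"] = sexes

    state["reads"] = reads
    state["truth"] = truth
    path = out / "truth.json"
    sio.write_json(path, dataclasses.asdict(truth))
    record("simulate", path)


def _load_catalog(path: str) -> list[cat.SatRecord]:
    records = []
    for name, seq in sio.read_fasta(path):
        try:
            prefix, rank, rul = cat.parse_sat_name(name)
        except ValueError:
            prefix, rank, rul = name, len(records) + 1, len(seq)
        records.append(cat.SatRecord(name, prefix, rank, len(seq), seq))
    return records


def _stage_catalog(config, out, state, record) -> None:
    ccfg = config.get("catalog", {})
    if "a" in ccfg and "b" in ccfg:
        cat_a = _load_catalog(ccfg["a"])
        cat_b = _load_catalog(ccfg["b"])
    else:
        cat_a = cat_b = state.get("catalog") or _load_catalog(str(out / "catalog.fasta"))
    overlap = cat.compare_catalogs(
        cat_a, cat_b, family_threshold=float(ccfg.get("family_threshold", 50.0))
    )
    frame = pd.DataFrame(
        [
            {"id_a": r.id_a, "id_b": r.id_b, "identity": r.identity, "relation": r.relation}
            for r in overlap.relations
        ]
    )
    sio.write_tsv(out / "catalog_overlap.tsv", frame)
    sio.write_json(
        out / "catalog_overlap.json",
        {
            "shared_family_count": overlap.shared_family_count,
            "identical_pair_count": overlap.identical_pair_count,
            "n_pairs": len(overlap.relations),
        },
    )
    record("catalog", out / "catalog_overlap.tsv")
    record("catalog", out / "catalog_overlap.json")
    state["overlap"] = overlap


def _get_reads(state, out) -> dict[str, list[str]]:
    if "reads" in state:
        return state["reads"]
    reads = {}
    for path in sorted(Path(out).glob("*.fastq")):
        reads[path.stem] = sio.read_fastq(path)
    if not reads:
        raise StageError("no read libraries available; run the simulate stage first")
    return reads


def _stage_abundance(config, seed, out, state, record) -> None:
    acfg = config.get("abundance", {})
    catalog = state.get("catalog") or _load_catalog(
        acfg.get("catalog", str(out / "catalog.fasta"))
    )
    reads = _get_reads(state, out)
    results = {}
    for lib, lib_reads in reads.items():
        res = ab.map_reads(
            lib_reads,
            catalog,
            library=lib,
            min_identity=float(acfg.get("min_identity", ab.DEFAULT_MIN_IDENTITY)),
            min_aligned=int(acfg.get("min_aligned", ab.DEFAULT_MIN_ALIGNED)),
            subsample=acfg.get("subsample"),
            seed=seed,
        )
        results[lib] = res
        frame = pd.DataFrame([dataclasses.asdict(r) for r in res])
        path = out / f"abundance_{lib}.tsv"
        sio.write_tsv(path, frame)
        record("abundance", path)
    state["abundance"] = results

    by_sex: dict[str, list] = {"M": [], "F": []}
    for lib, res in results.items():
        by_sex[_library_sex(lib)].extend(res)
    if by_sex["M"] and by_sex["F"]:
        # aggregate per satDNA across same-sex libraries by mean abundance
        def aggregate(res_list):
            agg: dict[str, list[float]] = {}
            for r in res_list:
                agg.setdefault(r.sat_name, []).append(r.abundance)
            return [
                ab.MappingResult(name, "agg", 0, 0, 0, sum(v) / len(v), 0.0)
                for name, v in agg.items()
            ]

        table = ab.sex_ratio(
            aggregate(by_sex["M"]),
            aggregate(by_sex["F"]),
            candidate_threshold=float(acfg.get("candidate_threshold", 1.5)),
        )
        frame = pd.DataFrame(table.rows)
        path = out / "sex_ratio.tsv"
        sio.write_tsv(path, frame)
        record("abundance", path)
        state["sex_ratio"] = table


def _stage_haplotypes(config, seed, out, state, record) -> None:
    hcfg = config.get("haplotypes", {})
    catalog = state.get("catalog") or _load_catalog(
        hcfg.get("catalog", str(out / "catalog.fasta"))
    )
    target = hcfg.get("target")
    if target is None and "target_family" in hcfg:
        target = state.get("sat_names", {}).get(hcfg["target_family"])
        if target is None:
            raise StageError(
                f"family {hcfg['target_family']!r} unknown (simulate stage not run?)"
            )
    if target is None:
        rec = catalog[0]
    else:
        matches = [r for r in catalog if r.name == target]
        if not matches:
            raise StageError(f"target satDNA {target!r} not in catalog")
        rec = matches[0]
    reads = _get_reads(state, out)
    monomers: list[hap.Monomer] = []
    for lib, lib_reads in sorted(reads.items()):
        monomers.extend(
            hap.extract_monomers(
                lib_reads,
                rec.consensus,
                library=lib,
                min_identity=float(hcfg.get("min_identity", 80.0)),
                subsample=hcfg.get("subsample"),
                seed=seed,
            )
        )
    nodes = hap.filter_singletons(monomers)
    if not nodes:
        raise StageError(f"no non-singleton haplotypes recovered for {rec.name}")
    graph = hap.build_mst(nodes)
    groups = hcfg.get("groups") or _default_groups(sorted(reads))
    stats = hap.group_stats(graph, groups)

    libs = sorted({lib for nd in nodes for lib in nd.counts})
    node_rows = [
        {"sequence": nd.sequence, "total": nd.total, **{lib: nd.counts.get(lib, 0) for lib in libs}}
        for nd in nodes
    ]
    sio.write_tsv(out / "haplotype_nodes.tsv", pd.DataFrame(node_rows))
    edge_rows = [{"from": i, "to": j, "steps": w} for i, j, w in graph.edges]
    sio.write_tsv(out / "haplotype_edges.tsv", pd.DataFrame(edge_rows))
    import networkx as nx

    nx.write_graphml(hap.to_networkx(graph), out / "haplotype_mst.graphml")
    sio.write_json(out / "haplotype_stats.json", {"sat_name": rec.name, **stats})
    for name in ("haplotype_nodes.tsv", "haplotype_edges.tsv",
                 "haplotype_mst.graphml", "haplotype_stats.json"):
        record("haplotypes", out / name)
    state["haplotype_graph"] = graph
    state["haplotype_stats"] = stats


def _stage_slm(config, out, state, record) -> None:
    scfg = config.get("slm", {})
    if "genotypes" in state:
        matrix, sexes = state["genotypes"], state["sexes"]
    else:
        matrix = sio.read_genotype_csv(scfg.get("genotypes", str(out / "genotypes.csv")))
        sexes = sio.read_sex_map(scfg.get("sexmap", str(out / "sexmap.csv")))
    result = slm_mod.analyze(
        matrix,
        sexes,
        max_missing=int(scfg.get("max_missing", 0)),
        het_prob=scfg.get("het_prob", "auto"),
        alpha_margin=float(scfg.get("alpha_margin", 0.05)),
    )
    rows = [{"locus": l, "pattern": "XY"} for l in result.xy_loci]
    rows += [{"locus": l, "pattern": "ZW"} for l in result.zw_loci]
    sio.write_tsv(out / "slm_report.tsv", pd.DataFrame(rows, columns=["locus", "pattern"]))
    sio.write_json(
        out / "slm_verdict.json",
        {
            "n_xy": len(result.xy_loci),
            "n_zw": len(result.zw_loci),
            "expected_by_chance_xy": result.expected_by_chance_xy,
            "expected_by_chance_zw": result.expected_by_chance_zw,
            "n_loci_scanned": result.n_loci_scanned,
            "het_prob": result.het_prob,
            "p_xy": result.p_xy,
            "p_zw": result.p_zw,
            "verdict": result.verdict,
        },
    )
    record("slm", out / "slm_report.tsv")
    record("slm", out / "slm_verdict.json")
    state["slm"] = result
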
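"""End-to-end orchestration: simulate -> map -> segregate -> conserve.

Configuration is a flat key=value text file (one pair per line, '#'
comments); unknown keys are rejected so typos never silently change a
run. Every output file carries a header naming the config hash that
produced it, and a JSON manifest records input checksums and outputs, so
identical inputs + config + seed regenerate an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .conservation import conserved_column_scan, map_cdna_variant, pairwise_identity
from .homozygosity import (
    ConsistencyRuleSet,
    apply_consistency_filter,
    evidence_matrix,
    gene_overlap,
    region_report,
    shared_homozygosity_scan,
)
from .model import PedmapError
from .segregation import carrier_frequency, classify_compatibility, concordance
from .sim import SimulationConfig, simulate_study_family

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_MISSING_INPUT = 3
EXIT_STAGE_FAILURE = 4

KNOWN_KEYS = {
    "seed", "out_dir", "stages",
    # simulate
    "sim_n_markers", "sim_missing_rate", "sim_causal_chrom", "sim_causal_bp",
    "sim_ancestral_segment_mb", "sim_recomb_rate",
    # map
    "ped", "map", "affected", "obligate_carriers", "declared_carriers",
    "unaffected_relatives", "min_markers", "merge_gap_bp", "tolerance",
    "max_missing_run", "genes", "slop_bp",
    # segregate / carriers
    "pedigree_table", "variants", "panel", "exclude",
    # conserve
    "cds", "cds_pos", "cds_ref", "cds_alt", "msa", "msa_reference",
    "window", "residue", "identity_a", "identity_b",
}

ALL_STAGES = ("simulate", "map", "segregate", "carriers", "conserve")


@dataclass
class PipelineConfig:
    values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - KNOWN_KEYS
        if unknown:
            raise PedmapError(f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PedmapError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        return cls(values)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.values.get(key, default)

    def require(self, key: str) -> str:
        if key not in self.values:
            raise PedmapError(f"config key {key!r} required for enabled stage")
        return self.values[key]

    def ids(self, key: str) -> tuple[str, ...]:
        raw = self.values.get(key, "")
        return tuple(x for x in (s.strip() for s in raw.split(",")) if x)

    @property
    def seed(self) -> int:
        return int(self.values.get("seed", "0"))

    @property
    def stages(self) -> tuple[str, ...]:
        raw = self.values.get("stages", ",".join(ALL_STAGES))
        stages = tuple(s.strip() for s in raw.split(",") if s.strip())
        bad = set(stages) - set(ALL_STAGES)
        if bad:
            raise PedmapError(f"unknown stages: {sorted(bad)}")
        # dependency order regardless of listing order
        return tuple(s for s in ALL_STAGES if s in stages)

    def hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derivation (< 2**31) so stages rerun in
    isolation reproducibly."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.hash()}\n")
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out_dir = Path(config.get("out_dir", "pedmap_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "config": dict(sorted(config.values.items())),
        "stages": {},
        "warnings": [],
    }
    inputs: dict[str, str] = {}
    outputs: list[str] = []

    ped_path = config.get("ped")
    map_path = config.get("map")

    if "simulate" in config.stages:
        sim_config = SimulationConfig(
            n_markers=int(config.get("sim_n_markers", "8000")),
            missing_rate=float(config.get("sim_missing_rate", "0.04")),
            causal_chrom=config.get("sim_causal_chrom", "C2"),
            causal_bp=int(config.get("sim_causal_bp", "139000000")),
            ancestral_segment_mb=float(config.get("sim_ancestral_segment_mb", "20")),
            recomb_rate_cm_per_mb=float(config.get("sim_recomb_rate", "1.0")),
            seed=stage_seed(config.seed, "simulate"),
        )
        fam = simulate_study_family(sim_config)
        ped_file, map_file = pio.write_plink(fam.pedigree, fam.genotypes, out_dir / "simulated")
        pio.write_pedigree_table(fam.pedigree, out_dir / "simulated_pedigree.tsv")
        ped_path, map_path = str(ped_file), str(map_file)
        outputs += [ped_path, map_path, str(out_dir / "simulated_pedigree.tsv")]
        manifest["stages"]["simulate"] = {
            "n_markers": len(fam.genotypes.marker_map),
            "causal_marker": fam.genotypes.marker_map.table["id"].iloc[fam.causal_marker_index],
            "seed": sim_config.seed,
        }

    if "map" in config.stages:
        if not ped_path or not map_path:
            raise FileNotFoundError("map stage requires ped= and map= (or the simulate stage)")
        inputs["ped"] = _checksum(Path(ped_path))
        inputs["map"] = _checksum(Path(map_path))
        pedigree, genotypes = pio.read_plink(ped_path, map_path)
        affected = list(config.ids("affected")) or [
            i.id for i in pedigree if i.phenotype == "affected"
        ]
        rules = ConsistencyRuleSet(
            obligate_carrier_ids=config.ids("obligate_carriers"),
            declared_carrier_ids=config.ids("declared_carriers"),
            unaffected_ids=config.ids("unaffected_relatives"),
            tolerance=int(config.get("tolerance", "0")),
        )
        if not rules.all_ids():
            # default: parents of affecteds are obligate carriers, all other
            # unaffected genotyped relatives constrain by non-homozygosity
            parents = {p for i in pedigree if i.phenotype == "affected" and i.sire
                       for p in (i.sire, i.dam)}
            others = [i.id for i in pedigree
                      if i.phenotype == "unaffected" and i.id not in parents
                      and i.id in genotypes.individual_ids]
            rules = ConsistencyRuleSet(
                obligate_carrier_ids=tuple(sorted(parents)),
                unaffected_ids=tuple(sorted(others)),
                tolerance=int(config.get("tolerance", "0")),
            )
        rules.validate(affected)
        params = {
            "affected": ",".join(affected),
            "min_markers": int(config.get("min_markers", "20")),
            "merge_gap_bp": int(config.get("merge_gap_bp", "1000000")),
            "max_missing_run": int(config.get("max_missing_run", "5")),
            "tolerance": rules.tolerance,
        }
        segments = shared_homozygosity_scan(
            genotypes, affected,
            min_markers=params["min_markers"],
            max_missing_run=params["max_missing_run"],
            merge_gap_bp=params["merge_gap_bp"],
        )
        regions = apply_consistency_filter(segments, genotypes, rules)
        report = region_report(regions)
        _write_tsv(report, out_dir / "regions.tsv", config, params)
        report.to_json(out_dir / "regions.json", orient="records", indent=2)
        evidence = evidence_matrix(genotypes, affected, params["max_missing_run"])
        _write_tsv(evidence, out_dir / "evidence_matrix.tsv", config, params)
        outputs += [str(out_dir / n) for n in ("regions.tsv", "regions.json", "evidence_matrix.tsv")]
        manifest["stages"]["map"] = {
            "n_segments": len(segments),
            "n_consistent": int((report["status"] == "consistent").sum()),
            "params": params,
        }
        genes_path = config.get("genes")
        if genes_path:
            genes = pd.read_csv(genes_path, sep="\t")
            inputs["genes"] = _checksum(Path(genes_path))
            overlap = gene_overlap(regions, genes, slop_bp=int(config.get("slop_bp", "0")))
            _write_tsv(overlap, out_dir / "gene_overlap.tsv", config, params)
            outputs.append(str(out_dir / "gene_overlap.tsv"))
            manifest["stages"]["map"]["n_candidate_genes"] = len(overlap)

    if "segregate" in config.stages:
        pedigree = pio.read_pedigree_table(config.require("pedigree_table"))
        table = pio.read_variant_table(config.require("variants"))
        inputs["pedigree_table"] = _checksum(Path(config.require("pedigree_table")))
        inputs["variants"] = _checksum(Path(config.require("variants")))
        verdicts = classify_compatibility(pedigree, table)
        pct, incompatible = concordance(verdicts)
        df = pd.DataFrame([v.__dict__ for v in verdicts])
        _write_tsv(df, out_dir / "segregation.tsv", config, {"concordance_pct": pct})
        outputs.append(str(out_dir / "segregation.tsv"))
        manifest["stages"]["segregate"] = {
            "concordance_pct": pct,
            "n_typed": len([v for v in verdicts if v.expectation != "untyped"]),
            "incompatible": [v.individual_id for v in incompatible],
        }

    if "carriers" in config.stages:
        panel_path = config.get("panel") or config.require("variants")
        table = pio.read_variant_table(panel_path)
        inputs["panel"] = _checksum(Path(panel_path))
        exclude = config.ids("exclude")
        stats = carrier_frequency(table, exclude_ids=exclude)
        df = pd.DataFrame([{
            "panel": stats.label, "n_total": stats.n_total,
            "n_hom_ref": stats.n_hom_ref, "n_het": stats.n_het,
            "n_hom_alt": stats.n_hom_alt, "carrier_pct": stats.carrier_pct,
            "ci95_low": stats.ci95[0], "ci95_high": stats.ci95[1],
        }])
        _write_tsv(df, out_dir / "carriers.tsv", config, {"exclude": ",".join(exclude)})
        outputs.append(str(out_dir / "carriers.tsv"))
        manifest["stages"]["carriers"] = {
            "carrier_pct": stats.carrier_pct, "n_total": stats.n_total,
        }

    if "conserve" in config.stages:
        result: dict = {}
        if config.get("cds"):
            cds = next(iter(pio.read_fasta(config.require("cds")).values()))
            inputs["cds"] = _checksum(Path(config.require("cds")))
            mapping = map_cdna_variant(
                int(config.require("cds_pos")), config.require("cds_ref"),
                config.require("cds_alt"), cds,
            )
            result["variant"] = {
                "hgvs_c": mapping.hgvs_c, "hgvs_p": mapping.hgvs_p,
                "codon_index": mapping.codon_index,
                "ref_codon": mapping.ref_codon, "alt_codon": mapping.alt_codon,
            }
        if config.get("identity_a") and config.get("identity_b"):
            seq_a = next(iter(pio.read_fasta(config.require("identity_a")).values()))
            seq_b = next(iter(pio.read_fasta(config.require("identity_b")).values()))
            result["identity"] = pairwise_identity(seq_a, seq_b)
        if config.get("msa"):
            aln = pio.read_aligned_fasta(config.require("msa"))
            inputs["msa"] = _checksum(Path(config.require("msa")))
            window = None
            if config.get("window"):
                lo, _, hi = config.require("window").partition(":")
                window = (int(lo), int(hi))
            profile, matching = conserved_column_scan(
                aln, config.require("msa_reference"), window=window,
                residue_predicate=config.get("residue"),
            )
            result["conservation"] = {
                "window": list(profile.window),
                "n_matching": len(matching),
                "matching_residues": matching,
            }
        path = out_dir / "conservation.json"
        path.write_text(json.dumps({"config_hash": config.hash(), **result}, indent=2))
        outputs.append(str(path))
        manifest["stages"]["conserve"] = result

    manifest["inputs"] = inputs
    manifest["outputs"] = sorted(outputs)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
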
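"""End-to-end orchestration: config in, TSV/JSON artifacts plus manifest out.

The pipeline runs the sequence stages (conservation scan, fingerprint
scoring and census, emission entropy, optional DCA) and the structure
stages (distograms, aromatic cores, contacts) in dependency order from a
single declarative YAML/JSON config, writing every artifact under one
output directory together with a :class:`RunManifest` recording the tool
version, a config hash, input checksums, per-stage outputs, seeds and
collected warnings.  Re-running with identical config and inputs
reproduces identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .msa import read_msa, column_profiles, conservation_scan, gap_pattern_profile
from .fingerprint import FingerprintDefinition, census, score_msa, scores_to_frame
from .entropy import entropy_table
from .structure import (SeqStructMap, distance_matrix, distogram_stats,
                        feature_select_positions, read_structure)
from .aromatic import HelixAnnotation, detect_aromatic_core, residue_contacts
from .dca import coupling_scores, fit_plmdca

logger = logging.getLogger(__name__)

_TOP_KEYS = {"msa", "conservation", "fingerprint", "entropy", "gap_profile",
             "dca", "structures", "distogram", "aromatic_core", "contacts",
             "seed", "out_dir"}


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    needs_msa = {"conservation", "fingerprint", "entropy", "gap_profile", "dca",
                 "distogram"}
    if needs_msa & set(cfg) and "msa" not in cfg:
        raise ConfigError("sequence stages require the 'msa' key")
    if ("aromatic_core" in cfg or "contacts" in cfg or "distogram" in cfg) \
            and "structures" not in cfg:
        raise ConfigError("structure stages require the 'structures' key")
    for entry in cfg.get("structures", []):
        if "path" not in entry:
            raise ConfigError("each structures entry requires 'path'")


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                 dry_run: bool = False) -> RunManifest:
    """Run all configured stages; returns (and writes) the manifest."""
    if not isinstance(config, dict):
        cfg_text = Path(config).read_text()
        config = yaml.safe_load(cfg_text)
    validate_config(config)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    out = Path(out_dir or config.get("out_dir", "trpscan_out"))
    seed = int(config.get("seed", 0))
    manifest = RunManifest(__version__, cfg_hash, seed)

    stages = [k for k in ("conservation", "gap_profile", "fingerprint", "entropy",
                          "dca", "distogram", "aromatic_core", "contacts")
              if k in config]
    if dry_run:
        logger.info("dry run; would execute stages: %s", stages)
        manifest.warnings.append(f"dry-run: planned stages {stages}")
        return manifest
    out.mkdir(parents=True, exist_ok=True)

    msa = None
    if "msa" in config:
        msa_cfg = config["msa"]
        msa_path = Path(msa_cfg["path"])
        if not msa_path.exists():
            raise FileNotFoundError(f"MSA input not found: {msa_path}")
        manifest.input_checksums[str(msa_path)] = _sha256(msa_path)
        labels = msa_cfg.get("labels")
        if labels is not None:
            manifest.input_checksums[str(labels)] = _sha256(labels)
        msa = read_msa(msa_path, labels)

    if "conservation" in config:
        c = config["conservation"] or {}
        scan = conservation_scan(msa, c.get("threshold", 0.90),
                                 c.get("phi", True))
        path = out / "conserved_positions.tsv"
        with open(path, "w") as fh:
            fh.write("column\tconsensus\tidentity_percent\tclass_used\n")
            for p in scan:
                fh.write(f"{p.column_index}\t{p.consensus}\t"
                         f"{p.identity_percent:.4f}\t{p.class_used}\n")
        prof_path = out / "column_profiles.tsv"
        rows = column_profiles(msa)
        with open(prof_path, "w") as fh:
            fh.write("column\tconsensus\tidentity\tphi_identity\tgap_fraction\n")
            for p in rows:
                fh.write(f"{p.column_index}\t{p.consensus}\t{p.identity:.6f}\t"
                         f"{p.phi_identity:.6f}\t{p.gap_fraction:.6f}\n")
        manifest.outputs["conservation"] = [str(path), str(prof_path)]

    if "gap_profile" in config:
        df = gap_pattern_profile(msa)
        path = out / "gap_profile.tsv"
        df.to_csv(path, sep="\t")
        manifest.outputs["gap_profile"] = [str(path)]

    if "fingerprint" in config:
        f = config["fingerprint"] or {}
        fp = FingerprintDefinition.from_json(f["definition"]) \
            if f.get("definition") else FingerprintDefinition.default()
        scores = score_msa(msa, fp)
        sc_path = out / "fingerprint_scores.tsv"
        scores_to_frame(scores).to_csv(sc_path, sep="\t", index=False)
        cs_path = out / "fingerprint_census.tsv"
        census(scores).to_csv(cs_path, sep="\t")
        manifest.outputs["fingerprint"] = [str(sc_path), str(cs_path)]

    if "entropy" in config:
        e = config["entropy"] or {}
        df = entropy_table(msa, e.get("max_gap", 0.5), e.get("pseudocount", 1.0))
        path = out / "entropy.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest.outputs["entropy"] = [str(path)]

    if "dca" in config:
        d = config["dca"] or {}
        model = fit_plmdca(msa, d.get("lambda_h", 0.01), d.get("lambda_j", 0.01),
                           d.get("theta", 0.1),
                           max_iter=d.get("max_iter", 500),
                           allow_large=d.get("allow_large", False))
        path = out / "dca_scores.tsv"
        coupling_scores(model).ranked_pairs().to_csv(path, sep="\t", index=False)
        manifest.outputs["dca"] = [str(path)]

    structures = []
    for entry in config.get("structures", []):
        spath = Path(entry["path"])
        if not spath.exists():
            raise FileNotFoundError(f"structure input not found: {spath}")
        manifest.input_checksums[str(spath)] = _sha256(spath)
        structures.append((entry, read_structure(spath)))

    if "distogram" in config:
        d = config["distogram"] or {}
        positions = feature_select_positions(msa, d.get("min_presence", 0.96))
        matrices = []
        for entry, st in structures:
            smap = SeqStructMap.from_tsv(entry["map"])
            matrices.append(distance_matrix(st, smap, positions))
        dist = distogram_stats(matrices, positions)
        path = out / "distogram.tsv"
        dist.to_long_frame().to_csv(path, sep="\t", index=False)
        manifest.outputs["distogram"] = [str(path)]

    if "aromatic_core" in config:
        a = config["aromatic_core"] or {}
        paths = []
        for entry, st in structures:
            helix_cfg = entry.get("helices") or a.get("helices")
            if helix_cfg is None:
                raise ConfigError(f"no helix ranges for structure {st.structure_id}")
            if isinstance(helix_cfg, (str, Path)):
                with open(helix_cfg) as fh:
                    helix_cfg = yaml.safe_load(fh)
            chain = entry.get("chain") or next(iter(st.chains))
            ann = HelixAnnotation.from_ranges(
                st, chain, {k: tuple(v) for k, v in helix_cfg.items()})
            clusters, facing = detect_aromatic_core(
                st, ann, a.get("threshold", 5.0))
            report = {
                "structure": st.structure_id,
                "clusters": [
                    {"size": c.size,
                     "members": [f"{r.name} {r.chain}{r.author_number}"
                                 for r in c.members]}
                    for c in clusters
                ],
                "n_facing": sum(1 for r in facing if r.facing),
            }
            path = out / f"aromatic_core_{st.structure_id}.json"
            path.write_text(json.dumps(report, indent=1))
            paths.append(str(path))
        manifest.outputs["aromatic_core"] = paths

    if "contacts" in config:
        c = config["contacts"] or {}
        paths = []
        for entry, st in structures:
            contacts = residue_contacts(
                st, c.get("threshold_general", 4.0),
                c.get("threshold_pipi", 5.0),
                cross_chain=c.get("cross_chain", False))
            path = out / f"contacts_{st.structure_id}.tsv"
            with open(path, "w") as fh:
                fh.write("chain_i\tres_i\tchain_j\tres_j\tmin_dist\trule\n")
                for ct in contacts:
                    fh.write(f"{ct.res_a.chain}\t{ct.res_a.author_number}\t"
                             f"{ct.res_b.chain}\t{ct.res_b.author_number}\t"
                             f"{ct.min_distance:.4f}\t{ct.rule}\n")
            paths.append(str(path))
        manifest.outputs["contacts"] = paths

    for stage, paths in manifest.outputs.items():
        for p in paths:
            if not Path(p).exists():
                raise RuntimeError(f"stage {stage} claims missing output {p}")
    manifest.to_json(out / "manifest.json")
    return manifest
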
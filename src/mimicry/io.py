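"""Serialization and run manifests: genotypes, configs, reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .evolution import GAConfig, Genotype, GenotypeError, ga_config_from_dict, ga_config_to_dict
from .trial import TrialConfig, _config_from_dict, _config_to_dict


def save_genotype(genotype: Genotype, path) -> None:
    Path(path).write_text(json.dumps({"genes": genotype.genes.tolist()}, indent=2))


def load_genotype(path) -> Genotype:
    """Load and validate a genotype JSON; errors name the offending gene."""
    data = json.loads(Path(path).read_text())
    if "genes" not in data:
        raise GenotypeError(f"{path}: missing 'genes' field")
    genes = data["genes"]
    for i, v in enumerate(genes):
        if not isinstance(v, (int, float)) or not np.isfinite(v):
            raise GenotypeError(f"{path}: gene {i} is not a finite number ({v!r})")
    return Genotype(np.asarray(genes, dtype=float))


def save_trial_config(config: TrialConfig, path) -> None:
    Path(path).write_text(json.dumps(_config_to_dict(config), indent=2))


def load_trial_config(path) -> TrialConfig:
    return _config_from_dict(json.loads(Path(path).read_text()))


def save_ga_config(ga: GAConfig, path) -> None:
    Path(path).write_text(json.dumps(ga_config_to_dict(ga), indent=2))


def load_ga_config(path) -> GAConfig:
    return ga_config_from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run directory byte-for-byte."""

    version: str
    config: dict
    master_seed: int
    sub_seeds: dict
    files: dict  # relative path -> sha256


def write_manifest(run_dir, config: dict, master_seed: int, sub_seeds: dict | None = None) -> RunManifest:
    """Checksum every file in ``run_dir`` and write manifest.json."""
    run_dir = Path(run_dir)
    files = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__,
        config=config,
        master_seed=int(master_seed),
        sub_seeds=sub_seeds or {},
        files=files,
    )
    (run_dir / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest


def read_manifest(run_dir) -> RunManifest:
    data = json.loads((Path(run_dir) / "manifest.json").read_text())
    return RunManifest(**data)


def verify_manifest(run_dir) -> list[str]:
    """Return the relative paths whose checksums no longer match."""
    run_dir = Path(run_dir)
    manifest = read_manifest(run_dir)
    bad = []
    for rel, digest in manifest.files.items():
        p = run_dir / rel
        if not p.is_file() or _sha256(p) != digest:
            bad.append(rel)
    return bad
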
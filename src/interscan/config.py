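"""Study configuration: one YAML/JSON-serializable object for a whole run.

Bundles the file paths, scan settings, and (when simulating) the generator
parameters plus the master seed, so a run can be reproduced from its sidecar
file alone.  ``load(save(cfg)) == cfg`` round-trips exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .scan import ScanConfig

__all__ = ["StudyConfig", "save_config", "load_config"]


@dataclass
class StudyConfig:
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    snp_meta_path: str | None = None
    out_prefix: str = "interscan_out"
    scan: ScanConfig = field(default_factory=ScanConfig)
    # simulation parameters, used when genotypes_path is absent
    n_subjects: int | None = None
    genome_size: int | None = None
    maf_grid: str | None = None
    repeating_grid: str | None = None
    n_phenotypes: int | None = None
    master_seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> list[str]:
        """Return the referenced input paths that do not resolve."""
        missing = []
        for p in (self.genotypes_path, self.phenotypes_path, self.snp_meta_path):
            if p is not None and not Path(p).exists():
                missing.append(p)
        return missing


def save_config(cfg: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    data = asdict(cfg)
    data["scan"] = asdict(cfg.scan)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def load_config(path: str | Path) -> StudyConfig:
    data = yaml.safe_load(Path(path).read_text())
    scan = ScanConfig(**data.pop("scan"))
    return StudyConfig(scan=scan, **data)
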
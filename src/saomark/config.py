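"""Pipeline configuration: one flat namespace of every tunable.

A config can be loaded from a flat ``key = value`` text file and
overridden by CLI flags; the effective configuration is echoed into each
output directory as a provenance file sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class Config:
    # oligo selection
    oligo_len: int = 45
    step: int = 25
    kmer: int = 17
    max_mean_count: float = 1.5
    max_single_count: int = 4
    min_identity: float = 0.80
    dtm_min: float = 10.0
    na_mM: float = 50.0
    oligo_nM: float = 250.0
    # noref consensus
    flank: int = 100
    seed_len: int = 15
    band: int = 25
    min_cov: int = 3
    min_af: float = 0.7
    reach: int = 200
    # marker design
    max_gap: int = 500
    markers_per_chrom: int = 120
    use_snps: bool = False
    primer_tm_min: float = 52.0
    primer_tm_max: float = 60.0
    max_total_mm: int = 2
    max_3prime_mm: int = 0
    three_prime_window: int = 5
    max_product: int = 2000
    min_len_diff_frac: float = 0.025
    min_len_diff_bp: int = 10
    # simulation
    n_chrom: int = 3
    chrom_len: int = 100_000
    repeat_fraction: float = 0.2
    repeat_unit: int = 500
    gc: float = 0.5
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    indel_len_geom_p: float = 0.3
    max_indel: int = 15
    depth: float = 10.0
    read_len: int = 150
    paired: bool = True
    insert_mean: int = 400
    insert_sd: int = 40
    error_rate: float = 0.002
    hybrid_wild_chroms: str = "all"  # comma-separated chromosome ids or "all"
    # randomness
    seed: int = 42

    def save(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "Config":
        values: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                values[key] = _coerce(raw, getattr(defaults, key))
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes", "on")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw
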
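"""Run configuration: flat key/value text with sections (INI dialect).

A diff-friendly, non-executable format holding file paths, column
roles, every editing/QC threshold, model choices and the seed.  All
thresholds default to the conventional values of the analysis: call
rate 0.90, MAF 0.01, heterozygote difference 0.15, minimum CG size 10,
3.5-SD outlier cut, 0.5 % window relevance, accuracy cut-offs
0.35/0.30, offspring cut-offs 10/30.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths
    pedigree_file: str = ""
    phenotype_file: str = ""
    dosage_file: str = ""
    snp_map_file: str = ""
    output_dir: str = ""
    # column roles
    factors: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)  # name -> max power
    random_effects: tuple = ("a",)
    # thresholds
    call_rate_min: float = 0.90
    maf_min: float = 0.01
    het_diff_max: float = 0.15
    min_cg: int = 10
    sd_cut: float = 3.5
    relevance_percent: float = 0.5
    acc_min_correlation: float = 0.35
    acc_min_ranking: float = 0.30
    min_offspring_ranking: int = 10
    min_offspring_trajectories: int = 30
    blend_weight: float = 0.05
    # model choices
    model: str = "auto"  # RNM1 / RNM2 / auto (AIC)
    include_x: bool = True
    cg_as_class: bool = False
    select_fixed: bool = False
    window_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("call_rate_min", 0.0, 1.0),
            ("maf_min", 0.0, 0.5),
            ("het_diff_max", 0.0, 1.0),
            ("blend_weight", 0.0, 1.0),
            ("sd_cut", 0.0, float("inf")),
            ("relevance_percent", 0.0, 100.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.model not in ("RNM1", "RNM2", "auto"):
            raise ValueError("model must be RNM1, RNM2 or auto")
        if "a" not in self.random_effects:
            raise ValueError("the additive effect must be fitted")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        kw: dict = {}
        sec = parser
        def get(section, key, conv=str):
            if parser.has_option(section, key):
                return conv(parser.get(section, key))
            return None
        for key in ("pedigree_file", "phenotype_file", "dosage_file",
                    "snp_map_file", "output_dir"):
            v = get("files", key)
            if v is not None:
                kw[key] = v
        v = get("columns", "factors")
        if v:
            kw["factors"] = [s.strip() for s in v.split(",") if s.strip()]
        v = get("columns", "covariates")
        if v:
            cov = {}
            for item in v.split(","):
                item = item.strip()
                if not item:
                    continue
                if "^" in item:
                    nm, p = item.split("^")
                    cov[nm] = max(int(p), cov.get(nm, 0))
                else:
                    cov[item] = max(1, cov.get(item, 0))
            kw["covariates"] = cov
        v = get("columns", "random_effects")
        if v:
            kw["random_effects"] = tuple(
                s.strip() for s in v.split(",") if s.strip()
            )
        floats = ("call_rate_min", "maf_min", "het_diff_max", "sd_cut",
                  "relevance_percent", "acc_min_correlation",
                  "acc_min_ranking", "blend_weight")
        ints = ("min_cg", "min_offspring_ranking",
                "min_offspring_trajectories", "window_size", "seed")
        bools = ("include_x", "cg_as_class", "select_fixed")
        for section in ("thresholds", "model"):
            if not parser.has_section(section):
                continue
            for key in parser.options(section):
                if key in floats:
                    kw[key] = parser.getfloat(section, key)
                elif key in ints:
                    kw[key] = parser.getint(section, key)
                elif key in bools:
                    kw[key] = parser.getboolean(section, key)
                elif key == "model":
                    kw["model"] = parser.get(section, key)
                else:
                    raise ValueError(f"unknown config key {section}.{key}")
        cfg = cls(**kw)
        base = Path(path).parent
        for key in ("pedigree_file", "phenotype_file", "dosage_file",
                    "snp_map_file"):
            v = getattr(cfg, key)
            if v:
                p = Path(v)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"{key}: {p}")
                setattr(cfg, key, str(p))
        return cfg
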
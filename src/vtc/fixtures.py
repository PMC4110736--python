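"""Seeded synthetic multi-sample VCF generator with ground-truth manifests.

The generator emulates a small cohort genotyped at independent biallelic and
multi-allelic sites: genotypes are drawn per site under Hardy–Weinberg
equilibrium at a configured minor-allele frequency, with tunable fractions of
indels, symbolic structural variants and multi-alternate records, plus
missing genotypes and read depths.  For association testing it can plant a
true allelic odds ratio by drawing case and control genotypes retrospectively
from group-specific allele frequencies.

Every run emits a :class:`Manifest` recording exactly what was written —
variant keys, per-alternate classes, the genotype matrix as serialized, and
case/control labels — so tests can compare parser and statistics output
against an independent ground truth.  The VCF text is written directly by
this module (not via :func:`vtc.vcf_model.write_vcf`), keeping generated
files an independent check on the package's reader and writer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "ManifestRecord",
    "Manifest",
    "PairManifest",
    "generate_vcf",
    "generate_pool_pair",
    "write_phenotypes",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``maf`` is the total alternate-allele frequency per site (split equally
    among alternates at multi-allelic sites).  ``planted_or`` switches label
    assignment from independent Bernoulli(0.5) to retrospective sampling:
    labels are drawn first, then genotypes with the control alternate
    frequency at ``maf`` and the case frequency set so the allelic odds ratio
    equals ``planted_or`` at every site.
    """

    seed: int = 0
    n_variants: int = 100
    n_samples: int = 3
    chroms: tuple[str, ...] = ("1", "2")
    maf: float = 0.2
    multi_alt_fraction: float = 0.1
    no_call_rate: float = 0.05
    indel_fraction: float = 0.1
    sv_fraction: float = 0.02
    dp_missing_rate: float = 0.05
    shared_fraction: float = 0.3
    planted_or: float | None = None
    sample_prefix: str = "s"

    def validate(self) -> None:
        if self.n_variants < 0 or self.n_samples < 0:
            raise ConfigError("n_variants and n_samples must be non-negative")
        if not self.chroms:
            raise ConfigError("at least one chromosome name is required")
        if not (0 < self.maf <= 0.5):
            raise ConfigError(f"maf must be in (0, 0.5], got {self.maf}")
        for name in ("multi_alt_fraction", "no_call_rate", "dp_missing_rate",
                     "shared_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.indel_fraction < 0 or self.sv_fraction < 0:
            raise ConfigError("class fractions must be non-negative")
        if self.indel_fraction + self.sv_fraction > 1:
            raise ConfigError("indel_fraction + sv_fraction must be <= 1")
        if self.planted_or is not None and self.planted_or <= 0:
            raise ConfigError(f"planted_or must be positive, got {self.planted_or}")

    @property
    def samples(self) -> list[str]:
        return [f"{self.sample_prefix}{i + 1}" for i in range(self.n_samples)]


@dataclass
class ManifestRecord:
    """Ground truth for one emitted record."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    classes: list[str]            # per alternate: snv / insertion / deletion / sv
    qual: float
    filter: str
    info: dict[str, object]
    genotypes: dict[str, str]     # sample -> GT string exactly as written
    depths: dict[str, int | None]

    @property
    def keys(self) -> list[tuple[str, int, str, str]]:
        return [(self.chrom, self.pos, self.ref, a) for a in self.alts]


@dataclass
class Manifest:
    """Exact description of one generated VCF."""

    config: GeneratorConfig
    samples: list[str]
    records: list[ManifestRecord]
    labels: dict[str, str] | None = None   # sample -> case/control
    true_or: float | None = None

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {k for rec in self.records for k in rec.keys}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": dataclasses.asdict(self.config),
            "samples": self.samples,
            "records": [dataclasses.asdict(r) for r in self.records],
            "labels": self.labels,
            "true_or": self.true_or,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class PairManifest:
    """Ground truth for a generated pool pair with controlled key overlap."""

    manifest_a: Manifest
    manifest_b: Manifest
    shared_keys: set[tuple[str, int, str, str]]


# ---------------------------------------------------------------------------
# Site and genotype sampling


def _draw_site(rng: np.random.Generator, cfg: GeneratorConfig,
               chrom: str, pos: int) -> tuple[str, list[str], list[str], dict]:
    """Draw (ref, alts, classes, info) for one site."""
    u = rng.random()
    base = _BASES[rng.integers(4)]
    if u < cfg.sv_fraction:
        svlen = int(rng.integers(100, 1000))
        return base, ["<DEL>"], ["sv"], {"SVTYPE": "DEL", "END": str(pos + svlen)}
    if u < cfg.sv_fraction + cfg.indel_fraction:
        tail = "".join(_BASES[i] for i in rng.integers(4, size=int(rng.integers(1, 6))))
        if rng.random() < 0.5:
            return base, [base + tail], ["insertion"], {}
        return base + tail, [base], ["deletion"], {}
    others = [b for b in _BASES if b != base]
    if rng.random() < cfg.multi_alt_fraction:
        alts = list(rng.choice(others, size=2, replace=False))
        return base, alts, ["snv", "snv"], {}
    return base, [others[rng.integers(3)]], ["snv"], {}


def _case_freq(maf: float, or_: float) -> float:
    odds = or_ * maf / (1 - maf)
    return odds / (1 + odds)


def _draw_genotype(rng: np.random.Generator, n_alts: int, p_alt_total: float,
                   no_call_rate: float) -> str:
    if no_call_rate > 0 and rng.random() < no_call_rate:
        return "./."
    p_each = p_alt_total / n_alts
    probs = [1 - p_alt_total] + [p_each] * n_alts
    a, b = rng.choice(n_alts + 1, size=2, p=probs)
    return f"{a}/{b}"


def _assign_labels(rng: np.random.Generator, cfg: GeneratorConfig) -> dict[str, str]:
    return {s: ("case" if rng.random() < 0.5 else "control") for s in cfg.samples}


def _plan_positions(rng: np.random.Generator, cfg: GeneratorConfig,
                    n_sites: int) -> list[tuple[str, int]]:
    """Sites spread over the configured chromosomes, strictly increasing
    positions within each chromosome."""
    chrom_of = rng.integers(len(cfg.chroms), size=n_sites)
    pos_state = {c: 0 for c in cfg.chroms}
    out = []
    for ci in chrom_of:
        chrom = cfg.chroms[ci]
        pos_state[chrom] += int(rng.integers(10, 500))
        out.append((chrom, 1000 + pos_state[chrom]))
    out.sort(key=lambda t: (cfg.chroms.index(t[0]), t[1]))
    return out


def _build_records(rng: np.random.Generator, cfg: GeneratorConfig,
                   sites: list[tuple[str, int, str, list[str], list[str], dict]],
                   labels: dict[str, str] | None) -> list[ManifestRecord]:
    records = []
    p_case = _case_freq(cfg.maf, cfg.planted_or) if cfg.planted_or else None
    for chrom, pos, ref, alts, classes, info in sites:
        genotypes: dict[str, str] = {}
        depths: dict[str, int | None] = {}
        for s in cfg.samples:
            if p_case is not None and labels is not None and labels[s] == "case":
                p = p_case
            else:
                p = cfg.maf
            genotypes[s] = _draw_genotype(rng, len(alts), p, cfg.no_call_rate)
            if cfg.dp_missing_rate > 0 and rng.random() < cfg.dp_missing_rate:
                depths[s] = None
            else:
                depths[s] = int(rng.poisson(30))
        qual = float(round(rng.uniform(20, 100), 1))
        records.append(ManifestRecord(
            chrom=chrom, pos=pos, ref=ref, alts=list(alts), classes=list(classes),
            qual=qual, filter="PASS", info=dict(info),
            genotypes=genotypes, depths=depths,
        ))
    return records


_HEADER_FIXED = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def _write_manifest_vcf(manifest: Manifest, path: Path) -> None:
    cfg = manifest.config
    lines = list(_HEADER_FIXED)
    for c in cfg.chroms:
        lines.append(f"##contig=<ID={c}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if manifest.samples:
        cols += ["FORMAT"] + manifest.samples
    lines.append("\t".join(cols))
    for rec in manifest.records:
        info = ";".join(f"{k}={v}" for k, v in rec.info.items()) or "."
        row = [rec.chrom, str(rec.pos), ".", rec.ref, ",".join(rec.alts),
               f"{rec.qual:g}", rec.filter, info]
        if manifest.samples:
            row.append("GT:DP")
            for s in manifest.samples:
                d = rec.depths[s]
                row.append(f"{rec.genotypes[s]}:{'.' if d is None else d}")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def generate_vcf(config: GeneratorConfig, out_path: str | Path) -> tuple[Path, Manifest]:
    """Write one synthetic VCF and its manifest; byte-identical per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _assign_labels(rng, config) if config.n_samples else None
    positions = _plan_positions(rng, config, config.n_variants)
    sites = []
    for chrom, pos in positions:
        ref, alts, classes, info = _draw_site(rng, config, chrom, pos)
        sites.append((chrom, pos, ref, alts, classes, info))
    records = _build_records(rng, config, sites, labels)
    manifest = Manifest(config=config, samples=config.samples, records=records,
                        labels=labels, true_or=config.planted_or)
    out_path = Path(out_path)
    _write_manifest_vcf(manifest, out_path)
    return out_path, manifest


def generate_pool_pair(
    config: GeneratorConfig, out_dir: str | Path,
    pool_ids: tuple[str, str] = ("A", "B"),
) -> tuple[Path, Path, PairManifest]:
    """Two synthetic VCFs whose variant-key overlap is controlled.

    Exactly ``round(shared_fraction * n_variants)`` sites (with identical
    REF/ALT) occur in both files; remaining sites are unique to each file.
    Genotypes are drawn independently per file, and each file gets its own
    sample roster (``<poolId>_s1`` ...), so genotype-level operations across
    the pair are non-trivial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    n_shared = round(config.shared_fraction * n)
    n_total = n_shared + 2 * (n - n_shared)

    positions = _plan_positions(rng, config, n_total)
    sites = []
    for chrom, pos in positions:
        ref, alts, classes, info = _draw_site(rng, config, chrom, pos)
        sites.append((chrom, pos, ref, alts, classes, info))
    assignment = rng.permutation(
        ["shared"] * n_shared + ["a"] * (n - n_shared) + ["b"] * (n - n_shared)
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    manifests: list[Manifest] = []
    for pid, tag in zip(pool_ids, ("a", "b")):
        own = [s for s, t in zip(sites, assignment) if t in ("shared", tag)]
        cfg = dataclasses.replace(config, sample_prefix=f"{pid}_s")
        labels = _assign_labels(rng, cfg) if cfg.n_samples else None
        records = _build_records(rng, cfg, own, labels)
        m = Manifest(config=cfg, samples=cfg.samples, records=records,
                     labels=labels, true_or=cfg.planted_or)
        path = out_dir / f"{pid}.vcf"
        _write_manifest_vcf(m, path)
        paths.append(path)
        manifests.append(m)

    shared_keys = {
        (chrom, pos, ref, alt)
        for (chrom, pos, ref, alts, _, _), t in zip(sites, assignment)
        if t == "shared"
        for alt in alts
    }
    return paths[0], paths[1], PairManifest(manifests[0], manifests[1], shared_keys)


def write_phenotypes(labels: dict[str, str], path: str | Path) -> Path:
    """Write case/control labels in the two-column 1=control/2=case format."""
    path = Path(path)
    with open(path, "w") as fh:
        for s, st in labels.items():
            fh.write(f"{s}\t{2 if st == 'case' else 1}\n")
    return path
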
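"""Seeded synthetic datasets with planted ground truth.

The generator emulates the statistical structure the analysis assumes for a
two-crop field experiment: a rainfall-tracking hub transcription factor
(an ERF-type "driver"), a set of driver-regulated targets whose response
sign can flip between the wet- and dry-season crops, flat low-expression
background genes, decoy genes that are significant in leaf tissue (and
therefore must be removed by leaf exclusion), and a mini-genome in which
each true target's promoter carries a planted cis-element (GCC-box by
default) while all other promoters are scrubbed of it.

Planted structure is recorded in :class:`SyntheticTruth` so recovery tests
can compare pipeline output against a known answer.  Everything is driven
by one integer seed and is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    ALL_CONDITIONS,
    AnnotationSet,
    CisElement,
    ConditionKey,
    ExpressionMatrix,
    GeneAnnotation,
    PrecipitationSeries,
    ROOT_CONDITIONS,
    SEASONS,
)
from .promoter import IUPAC, _iupac_regex, revcomp_iupac

GCC_BOX = CisElement(name="GCC-box", tf_family="AP2/EREBP", consensus="GCCGCC")
#: Extra, unplanted element shipped with the table for realism.
W_BOX = CisElement(name="W-box", tf_family="WRKY", consensus="TTGACY")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror the emulated design: 42 genes measured over 8 ordered
    timepoints in six condition tracks (cortex/parenchyma/leaf x wet/dry),
    one precipitation-driven hub regulator, and a 0.6 fraction of shared
    targets whose correlation sign flips between seasons.
    """

    n_genes: int = 42
    n_targets: int = 8
    n_timepoints: int = 8
    noise_sd: float = 0.1
    driver_gain: float = 1.0
    target_gain: float = 0.8
    target_baseline: float = 1.0
    background_level: float = 0.05
    flip_fraction: float = 0.6
    leaf_decoy_count: int = 3
    seed: int = 0
    promoter_len: int = 2000
    planted_element: CisElement = GCC_BOX
    noise_model: str = "truncnorm"  # or "lognormal"
    tissue_flip: bool = False
    multi_gene_contigs: bool = False
    driver_id: str = "ERF1"

    def validate(self) -> None:
        if not 0 <= self.flip_fraction <= 1:
            raise ValueError(f"flip_fraction must be in [0, 1], got {self.flip_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_targets >= self.n_genes:
            raise ValueError("n_targets must be smaller than n_genes")
        if self.n_targets + self.leaf_decoy_count + 1 > self.n_genes:
            raise ValueError("driver + targets + decoys exceed n_genes")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.noise_model not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery tests."""

    driver: str
    true_edges: dict[ConditionKey, set[tuple[str, str, int]]]
    leaf_decoys: set[str]
    planted_hits: dict[str, int]  # target -> offset of the planted element

    def edges_for(self, cond: ConditionKey) -> set[tuple[str, str, int]]:
        return self.true_edges.get(cond, set())


@dataclass
class GeneratedDataset:
    config: SynthConfig
    matrices: dict[ConditionKey, ExpressionMatrix]
    precipitation: dict[str, PrecipitationSeries]
    genome_fasta: str
    gff3: str
    annotations: AnnotationSet
    elements: list[CisElement]
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        """Emit exactly the file formats the pipeline consumes."""
        from pathlib import Path

        from .expression_io import write_expression, write_precipitation

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression(self.matrices, out / "expression.tsv")
        for season, series in self.precipitation.items():
            write_precipitation(series, out / f"precipitation_{season}.tsv")
        pd.DataFrame(
            [
                {
                    "id": a.id,
                    "description": a.description,
                    "is_tf": str(a.is_tf).lower(),
                    "tf_family": a.tf_family or "",
                }
                for a in self.annotations.annotations
            ]
        ).to_csv(out / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"name": e.name, "tf_family": e.tf_family, "iupac_consensus": e.consensus}
                for e in self.elements
            ]
        ).to_csv(out / "elements.tsv", sep="\t", index=False)
        (out / "genome.fa").write_text(self.genome_fasta)
        (out / "genes.gff3").write_text(self.gff3)
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "driver": self.truth.driver,
                    "true_edges": {
                        cond.label: sorted(list(e) for e in edges)
                        for cond, edges in sorted(self.truth.true_edges.items())
                    },
                    "leaf_decoys": sorted(self.truth.leaf_decoys),
                    "planted_hits": dict(sorted(self.truth.planted_hits.items())),
                },
                indent=2,
            )
            + "\n"
        )


def simulate_precipitation(
    season: str,
    n_timepoints: int,
    seed: int,
    peak_mm: float = 200.0,
    jitter_sd: float = 8.0,
) -> PrecipitationSeries:
    """Seasonal rainfall over the sampling timepoints.

    The wet-season crop is planted at the onset of rains, so rainfall is
    high early and decays across the growth period; the dry-season crop is
    planted at the end of rains, so rainfall starts low and rises towards
    the next rainy season.  Both are scaled half-cosine ramps of amplitude
    ``peak_mm`` plus seeded Gaussian jitter, clamped at zero; at zero
    jitter the two ramps are exactly anti-correlated.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    t = np.arange(n_timepoints)
    ramp = 0.5 + 0.5 * np.cos(np.pi * t / (n_timepoints - 1))  # 1 -> 0
    base = peak_mm * (ramp if season == "wet" else 1.0 - ramp)
    rng = np.random.default_rng([seed, 0 if season == "wet" else 1])
    values = np.maximum(base + rng.normal(0.0, jitter_sd, n_timepoints), 0.0)
    return PrecipitationSeries(timepoints=list(range(n_timepoints)), values=values, season=season)


def _noise(rng: np.random.Generator, base: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.maximum(base, 0.0)
    if cfg.noise_model == "truncnorm":
        return np.maximum(base + rng.normal(0.0, cfg.noise_sd, base.shape), 0.0)
    return np.maximum(base * rng.lognormal(0.0, cfg.noise_sd, base.shape), 0.0)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length)


_BASES = np.array(list("ACGT"))


def _scrub(seq: list[str], consensus: str, rng: np.random.Generator) -> None:
    """Remove every occurrence of the consensus (both strands) in place."""
    patterns = [_iupac_regex(consensus), _iupac_regex(revcomp_iupac(consensus))]
    text = "".join(seq)
    guard = 0
    while True:
        hit = None
        for pat in patterns:
            m = pat.search(text)
            if m and (hit is None or m.start() < hit):
                hit = m.start()
        if hit is None:
            break
        seq[hit] = str(rng.choice(_BASES))
        text = "".join(seq)
        guard += 1
        if guard > 10000:  # astronomically unlikely for any real consensus
            raise RuntimeError("could not scrub consensus from promoter")


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    """Pick one concrete realisation of an IUPAC consensus."""
    return "".join(str(rng.choice(list(IUPAC[c]))) for c in consensus.upper())


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_dataset(config: SynthConfig = SynthConfig()) -> GeneratedDataset:
    """Build the full six-track dataset plus mini-genome and truth record."""
    config.validate()
    cfg = config
    rng = np.random.default_rng([cfg.seed, 100])

    driver = cfg.driver_id
    targets = [f"T{i + 1:02d}" for i in range(cfg.n_targets)]
    decoys = [f"L{i + 1:02d}" for i in range(cfg.leaf_decoy_count)]
    n_background = cfg.n_genes - 1 - cfg.n_targets - cfg.leaf_decoy_count
    background = [f"B{i + 1:02d}" for i in range(n_background)]
    genes = sorted([driver] + targets + decoys + background)

    # planted response signs: base sign per target; a seeded subset flips
    # between the seasons (or between tissues in tissue_flip mode)
    base_sign = {t: int(s) for t, s in zip(targets, rng.choice([-1, 1], cfg.n_targets))}
    n_flip = int(round(cfg.flip_fraction * cfg.n_targets))
    flip_order = [targets[i] for i in rng.permutation(cfg.n_targets)]
    flipped = set(flip_order[:n_flip])

    def planted_sign(target: str, cond: ConditionKey) -> int:
        s = base_sign[target]
        if cfg.tissue_flip:
            return -s if (cond.tissue == "parenchyma" and target in flipped) else s
        return -s if (cond.season == "dry" and target in flipped) else s

    precipitation = {
        season: simulate_precipitation(season, cfg.n_timepoints, cfg.seed)
        for season in SEASONS
    }

    t = np.arange(cfg.n_timepoints)
    matrices: dict[ConditionKey, ExpressionMatrix] = {}
    true_edges: dict[ConditionKey, set[tuple[str, str, int]]] = {}
    for cond in sorted(ALL_CONDITIONS):
        precip = precipitation[cond.season]
        precip_norm = precip.values / precip.values.max()
        rows = {}
        if cond.is_root:
            driver_series = _noise(rng, cfg.driver_gain * precip_norm, cfg)
            rows[driver] = driver_series
            edges = set()
            for target in targets:
                s = planted_sign(target, cond)
                base = cfg.target_baseline + s * cfg.target_gain * driver_series
                rows[target] = _noise(rng, base, cfg)
                edges.add((driver, target, s))
            true_edges[cond] = edges
            for gene in decoys:
                phase = rng.uniform(0, 2 * np.pi)
                base = 1.0 + 0.5 * np.sin(2 * np.pi * t / cfg.n_timepoints + phase)
                rows[gene] = _noise(rng, base, cfg)
            for gene in background:
                rows[gene] = _noise(rng, np.full(cfg.n_timepoints, cfg.background_level), cfg)
        else:
            # leaf track: driver, targets and background are flat/low;
            # only the decoys are strongly and variably expressed
            for gene in [driver] + targets + background:
                rows[gene] = _noise(rng, np.full(cfg.n_timepoints, cfg.background_level), cfg)
            for gene in decoys:
                phase = rng.uniform(0, 2 * np.pi)
                base = 1.0 + 0.5 * np.sin(2 * np.pi * t / cfg.n_timepoints + phase)
                rows[gene] = _noise(rng, base, cfg)
            true_edges[cond] = set()
        values = pd.DataFrame(
            {tp: [rows[g][tp] for g in genes] for tp in range(cfg.n_timepoints)},
            index=pd.Index(genes, name="gene_id"),
        )
        matrices[cond] = ExpressionMatrix(condition=cond, values=values)

    annotations = AnnotationSet(
        [
            GeneAnnotation(
                id=driver,
                description="ethylene-responsive transcription factor (planted hub driver)",
                is_tf=True,
                tf_family=cfg.planted_element.tf_family,
            )
        ]
        + [GeneAnnotation(id=g, description="driver-responsive target") for g in targets]
        + [GeneAnnotation(id=g, description="leaf-expressed decoy") for g in decoys]
        + [GeneAnnotation(id=g, description="background gene") for g in background]
    )

    genome_fasta, gff3, planted_hits = _build_genome(cfg, genes, set(targets), rng)

    truth = SyntheticTruth(
        driver=driver,
        true_edges=true_edges,
        leaf_decoys=set(decoys),
        planted_hits=planted_hits,
    )
    return GeneratedDataset(
        config=cfg,
        matrices=matrices,
        precipitation=precipitation,
        genome_fasta=genome_fasta,
        gff3=gff3,
        annotations=annotations,
        elements=[cfg.planted_element, W_BOX],
        truth=truth,
    )


def _build_genome(
    cfg: SynthConfig, genes: list[str], targets: set[str], rng: np.random.Generator
) -> tuple[str, str, dict[str, int]]:
    """One contig per gene (default): promoter then CDS, strand alternating.

    True targets get one instance of the planted element inserted at a
    seeded offset; every other promoter position (and every non-target
    promoter) is scrubbed of the consensus on both strands.  With
    ``multi_gene_contigs`` all genes share one contig and the first gene's
    promoter is shortened so extraction exercises boundary truncation.
    """
    consensus = cfg.planted_element.consensus
    m = len(consensus)
    cds_len = 150
    fasta_parts: list[str] = []
    gff_lines = ["##gff-version 3"]
    planted_hits: dict[str, int] = {}
    contig_parts: list[str] = []
    offset_bp = 0  # running coordinate on the shared contig

    for idx, gene in enumerate(genes):
        promoter_len = cfg.promoter_len
        if cfg.multi_gene_contigs and idx == 0:
            promoter_len = min(150, cfg.promoter_len)
        promoter = list(_BASES[_random_seq(rng, promoter_len)])
        _scrub(promoter, consensus, rng)
        if gene in targets and promoter_len >= m:
            pos = int(rng.integers(0, promoter_len - m + 1))
            promoter[pos : pos + m] = list(_instantiate(consensus, rng))
            planted_hits[gene] = pos - promoter_len  # offset relative to TLS
        promoter_seq = "".join(promoter)
        cds_seq = "ATG" + "".join(
            _BASES[_random_seq(rng, cds_len - 6)]
        ) + "TGA"
        strand = "+" if idx % 2 == 0 else "-"
        oriented = promoter_seq + cds_seq
        segment = oriented if strand == "+" else _revcomp(oriented)
        if strand == "+":
            cds_start, cds_end = promoter_len + 1, promoter_len + cds_len
        else:
            cds_start, cds_end = 1, cds_len

        if cfg.multi_gene_contigs:
            chrom = "chr1"
            shift = offset_bp
            contig_parts.append(segment)
            offset_bp += len(segment)
        else:
            chrom = f"chr_{gene}"
            shift = 0
            fasta_parts.append(f">{chrom}\n{segment}\n")
        g_start, g_end = cds_start + shift, cds_end + shift
        attrs = f"ID={gene}"
        gff_lines.append(
            f"{chrom}\tseasonet\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t{attrs}"
        )
        gff_lines.append(
            f"{chrom}\tseasonet\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene}.1;Parent={gene}"
        )
        gff_lines.append(
            f"{chrom}\tseasonet\tCDS\t{g_start}\t{g_end}\t.\t{strand}\t0\tID={gene}.1.cds;Parent={gene}.1"
        )

    if cfg.multi_gene_contigs:
        fasta_parts.append(">chr1\n" + "".join(contig_parts) + "\n")
    return "".join(fasta_parts), "\n".join(gff_lines) + "\n", planted_hits
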
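"""Seeded generator of synthetic heterologous hybridization experiments.

The generator emulates the structure of a two-species genomic
hybridization onto a tiling array: a reference genome, 25-mer target
probes tiled along it at fixed spacing and grouped into genes (exon
probes) separated by intergenic probes, a set of foreign control probes
with no specific binding in any species, and a test species whose genome
is the reference mutated by substitutions, short indels, and planted
deletions.  Two chips per species carry independent log-normal noise.

The signal model for the ln intensity of probe p on a chip of species s:

    ln i = alpha_true + beta_true * ΔG37(p)
           + g(identity_s(p)) * (specific_effect + ln copies(p)) + N(0, sigma²)

where g rises linearly from 0 at ``identity_floor`` (default 20/25) to 1
at perfect identity: the non-specific component depends only on duplex
thermodynamics, while the specific component requires sequence identity
and scales with genomic copy number.  Control probes have g = 0 for
every species (they are equivalently dissimilar to all of them).  The
true identity-affinity map of short oligo duplexes is not claimed here;
g is a configuration knob.

Everything is driven by one integer seed; the same configuration and
seed reproduce the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .thermo import delta_g37_many

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "generate_dataset",
           "generate_ortholog_pair", "random_sequence"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic hybridization experiment."""

    n_target_probes: int = 2000
    n_control_probes: int = 500
    probe_length: int = 25
    probe_spacing_bp: int = 35
    alpha_true: float = 5.0
    beta_true: float = -0.15
    sigma_noise: float = 0.3
    specific_effect: float = 2.0
    identity_floor: float = 0.8
    divergence_per_site: float = 0.0
    indel_rate: float = 0.0
    deletion_intervals: tuple = ()
    copy_number: Mapping[int, int] | None = None  # target probe index -> copies
    chips_per_species: int = 2
    probes_per_gene: int = 8
    intergenic_gap_probes: int = 2
    conserved_fraction: float = 0.0  # genes shielded from mutation in the test species
    gc_content: float = 0.36
    exon_gc: float | None = None  # optional higher GC inside gene spans
    reference_species: str = "reference"
    test_species: str = "test"
    seed: int = 0


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded alongside the emitted data."""

    matches: pd.Series  # target probe_id -> identical nt vs the test genome
    conserved: dict  # gene_id -> bool (shielded from mutation)
    deletion_intervals: tuple  # (start, length) on the reference
    copies: pd.Series  # target probe_id -> genomic copy number


@dataclass(frozen=True)
class SimulatedDataset:
    probes: pd.DataFrame
    intensities: pd.DataFrame
    chips: pd.DataFrame
    genomes: dict
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return b"".join(rng.choice(_BASES, size=length, p=p)).decode()


def _random_bases(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def generate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate probes, genomes, and raw per-chip intensities.

    Reference probes are tiled every ``probe_spacing_bp`` bases; genes
    are consecutive blocks of ``probes_per_gene`` exon probes separated
    by ``intergenic_gap_probes`` intergenic probes.  The test genome is
    the reference with substitutions at ``divergence_per_site``, 1-bp
    indels at ``indel_rate`` (half deletions, half insertions of 1–3
    bases), and the planted ``deletion_intervals`` removed; genes drawn
    as conserved (``conserved_fraction``) are shielded from substitution
    and indel mutation, but not from planted deletions.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_target_probes * cfg.probe_spacing_bp + cfg.probe_length
    for start, length in cfg.deletion_intervals:
        if start < 0 or start + length > L:
            raise ValueError(
                f"deletion interval ({start}, {length}) outside genome of length {L}"
            )

    starts = np.arange(cfg.n_target_probes) * cfg.probe_spacing_bp

    # gene layout: blocks of exon probes separated by intergenic probes
    cycle = cfg.probes_per_gene + cfg.intergenic_gap_probes
    block = np.arange(cfg.n_target_probes) // cycle
    within = np.arange(cfg.n_target_probes) % cycle
    is_exon = within < cfg.probes_per_gene
    gene_idx = np.where(is_exon, block, -1)
    n_genes = int(block[is_exon].max()) + 1 if is_exon.any() else 0
    gene_ids = np.array([f"gene_{g:05d}" for g in range(n_genes)])

    # reference genome, optionally GC-biased inside gene spans
    ref = _random_bases(rng, L, cfg.gc_content)
    gene_mask = np.zeros(L, dtype=bool)
    for g in range(n_genes):
        sel = np.flatnonzero(gene_idx == g)
        gene_mask[starts[sel[0]] : starts[sel[-1]] + cfg.probe_length] = True
    if cfg.exon_gc is not None:
        ref[gene_mask] = _random_bases(rng, int(gene_mask.sum()), cfg.exon_gc)

    conserved_genes = rng.random(n_genes) < cfg.conserved_fraction
    shield = np.zeros(L, dtype=bool)
    for g in np.flatnonzero(conserved_genes):
        sel = np.flatnonzero(gene_idx == g)
        shield[starts[sel[0]] : starts[sel[-1]] + cfg.probe_length] = True

    # mutate the reference into the test genome
    planted_del = np.zeros(L, dtype=bool)
    for start, length in cfg.deletion_intervals:
        planted_del[start : start + length] = True
    sub_mask = (rng.random(L) < cfg.divergence_per_site) & ~shield & ~planted_del
    indel_pos = (rng.random(L) < cfg.indel_rate) & ~shield & ~planted_del
    indel_is_del = rng.random(L) < 0.5
    indel_del = indel_pos & indel_is_del
    has_insert = indel_pos & ~indel_is_del

    test = ref.copy()
    if sub_mask.any():
        # substituted base differs from the original
        test[sub_mask] = (ref[sub_mask] + rng.integers(1, 4, sub_mask.sum())) % 4
    keep = ~(planted_del | indel_del)
    out = test[keep]
    ins_sites = np.flatnonzero(has_insert)
    if ins_sites.size:
        # insertion of 1-3 random bases before each site, in output coordinates
        out_index = np.cumsum(keep) - 1
        chunks, prev = [], 0
        for site in ins_sites:
            at = out_index[site] + (1 if keep[site] else 0)
            chunks.append(out[prev:at])
            chunks.append(_random_bases(rng, int(rng.integers(1, 4)), cfg.gc_content))
            prev = at
        chunks.append(out[prev:])
        out = np.concatenate(chunks)
    genomes = {
        cfg.reference_species: b"".join(_BASES[ref]).decode(),
        cfg.test_species: b"".join(_BASES[out]).decode(),
    }

    # per-probe identity of the test species vs the reference probes
    mismatch = sub_mask | planted_del | indel_del
    cmis = np.concatenate([[0], np.cumsum(mismatch)])
    matches = cfg.probe_length - (cmis[starts + cfg.probe_length] - cmis[starts])

    # probe table
    tgt_ids = np.array([f"t{j:06d}" for j in range(cfg.n_target_probes)])
    ref_str = genomes[cfg.reference_species]
    tgt_seqs = [ref_str[s : s + cfg.probe_length] for s in starts]
    ctl_ids = np.array([f"c{j:06d}" for j in range(cfg.n_control_probes)])
    ctl_seqs = [
        random_sequence(rng, cfg.probe_length, cfg.gc_content)
        for _ in range(cfg.n_control_probes)
    ]
    probes = pd.DataFrame(
        {
            "probe_id": np.concatenate([tgt_ids, ctl_ids]),
            "sequence": tgt_seqs + ctl_seqs,
            "chromosome": ["chrI"] * cfg.n_target_probes
            + ["control_set"] * cfg.n_control_probes,
            "start": np.concatenate(
                [starts, np.arange(cfg.n_control_probes) * cfg.probe_length]
            ),
            "category": ["target"] * cfg.n_target_probes
            + ["control"] * cfg.n_control_probes,
            "control_origin": [None] * cfg.n_target_probes
            + [("plant" if j % 2 == 0 else "bacterial") for j in range(cfg.n_control_probes)],
            "gene_id": [gene_ids[g] if g >= 0 else None for g in gene_idx]
            + [None] * cfg.n_control_probes,
            "region": [("exon" if g >= 0 else "intergenic") for g in gene_idx]
            + [None] * cfg.n_control_probes,
        }
    )

    copies = np.ones(cfg.n_target_probes)
    if cfg.copy_number:
        for j, c in cfg.copy_number.items():
            copies[j] = c

    # intensities: two chips per species with independent noise
    dg = delta_g37_many(probes["sequence"].tolist())
    ident_frac = matches / cfg.probe_length
    floor = cfg.identity_floor
    g_test_tgt = np.clip((ident_frac - floor) / (1 - floor), 0.0, 1.0)
    g = {
        cfg.reference_species: np.concatenate(
            [np.ones(cfg.n_target_probes), np.zeros(cfg.n_control_probes)]
        ),
        cfg.test_species: np.concatenate(
            [g_test_tgt, np.zeros(cfg.n_control_probes)]
        ),
    }
    copies_all = np.concatenate([copies, np.ones(cfg.n_control_probes)])
    specific = cfg.specific_effect + np.log(copies_all)
    chip_rows, int_frames = [], []
    for species in (cfg.reference_species, cfg.test_species):
        for rep in range(1, cfg.chips_per_species + 1):
            chip_id = f"{species}_rep{rep}"
            noise = rng.normal(0.0, cfg.sigma_noise, len(dg))
            ln_i = cfg.alpha_true + cfg.beta_true * dg + g[species] * specific + noise
            int_frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probes["probe_id"],
                        "chip_id": chip_id,
                        "intensity": np.exp(ln_i),
                    }
                )
            )
            chip_rows.append({"chip_id": chip_id, "species": species, "replicate": rep})

    truth = SimTruth(
        matches=pd.Series(matches, index=tgt_ids, name="matches"),
        conserved={gene_ids[g]: bool(conserved_genes[g]) for g in range(n_genes)},
        deletion_intervals=tuple(cfg.deletion_intervals),
        copies=pd.Series(copies, index=tgt_ids, name="copies"),
    )
    return SimulatedDataset(
        probes=probes,
        intensities=pd.concat(int_frames, ignore_index=True),
        chips=pd.DataFrame(chip_rows),
        genomes=genomes,
        truth=truth,
        config=cfg,
    )


def generate_ortholog_pair(
    length: int,
    divergence_per_site: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    gc: float = 0.36,
) -> tuple[str, str, tuple[str, str]]:
    """A reference sequence, a mutated ortholog, and their true alignment.

    Substitutions occur independently per site at ``divergence_per_site``
    (the substituted base always differs); indels at ``indel_rate`` are
    1-bp deletions or insertions of 1–3 bases with equal probability.
    The returned gapped pair is the alignment implied by the generative
    history, suitable for validating alignment and identity scoring.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    ref = _random_bases(rng, length, gc)
    ga, gb = [], []
    for i in range(length):
        base = _BASES[ref[i]].decode()
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:  # deletion in the ortholog
                ga.append(base)
                gb.append("-")
                continue
            ins = b"".join(
                _BASES[_random_bases(rng, int(rng.integers(1, 4)), gc)]
            ).decode()
            ga.append("-" * len(ins))
            gb.append(ins)
        if rng.random() < divergence_per_site:
            alt = _BASES[(ref[i] + rng.integers(1, 4)) % 4].decode()
            ga.append(base)
            gb.append(alt)
        else:
            ga.append(base)
            gb.append(base)
    gapped_a, gapped_b = "".join(ga), "".join(gb)
    return (
        gapped_a.replace("-", ""),
        gapped_b.replace("-", ""),
        (gapped_a, gapped_b),
    )
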
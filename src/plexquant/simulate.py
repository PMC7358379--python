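"""Ground-truthed synthetic two-plex TMT datasets.

The generator emulates a six-group (five treatments + vehicle control),
three-replicate study split across two 11-channel TMT plexes, each
carrying two pooled-reference channels mixed equally from all 18 samples.
Its statistical structure mirrors what the analysis assumes:

* per-protein baseline abundances, log-uniform over decades;
* multiplicative log-normal channel noise (σ default 0.02, putting pooled
  channel CVs in the few-percent regime);
* a fraction of proteins truly perturbed per treatment, with modest
  effect ratios (default uniform in 1.15–2, up/down mixed);
* plex-level batch scale factors (absorbed by the pooled reference);
* whole-protein per-plex dropout (a protein undetected in one MS run is
  absent from that plex's export);
* pathway memberships that include annotated-but-undetectable members, so
  percent coverage is meaningfully below 100; one pathway per treatment
  is *planted* — preferentially populated from that treatment's true
  differential set.

Reporter intensities are rounded to integers, like the count-like summed
intensities of vendor protein-level exports; with baselines ≥ 1e5 the
rounding is far below the channel noise.  Everything is reproducible from
(parameters, seed): the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import design as dio
from .design import Channel, PathwayAnnotation, PlexDesign, ReporterIntensityTable
from .pathways import FUNCTIONAL_CLASSES

#: 11-plex TMT reporter labels
TMT11_LABELS = (
    "126", "127N", "127C", "128N", "128C", "129N",
    "129C", "130N", "130C", "131N", "131C",
)

DEFAULT_TREATMENTS = ("FCCP", "dinoterb", "picoxystrobin", "pinacyanol", "triclocarban")
DEFAULT_CONTROL = "DMSO"

#: share of a planted pathway's detectable members drawn from the
#: treatment's true differential set
PLANTED_DE_FRACTION = 0.7

#: share of each pathway's annotated members that are outside the
#: measurable proteome (annotated but never detected)
PHANTOM_FRACTION = 0.35


@dataclass
class GroundTruth:
    """Complete generative state of one synthetic dataset."""

    seed: int
    accessions: list[str]
    baseline: np.ndarray  # positive, aligned with accessions
    effects: pd.DataFrame  # accession x treatment true ratios (1.0 = null)
    de_sets: dict[str, set[str]]
    pathways: list[PathwayAnnotation]
    planted: dict[str, str]  # treatment -> planted pathway_id
    mito: set[str]
    classes: dict[str, str]  # functional class of mitochondrial proteins
    localization: dict[str, str]
    plex_scale: dict[str, float]
    sigma: float
    dropout: float
    control: str
    params: dict = field(default_factory=dict)

    @property
    def treatments(self) -> list[str]:
        return list(self.effects.columns)

    def effect(self, accession_idx: np.ndarray | slice, group: str) -> np.ndarray:
        """True expression ratio of a group vs baseline (1.0 for control
        and for any group without planted effects)."""
        if group in self.effects.columns:
            return self.effects[group].to_numpy()[accession_idx]
        n = len(self.accessions) if isinstance(accession_idx, slice) else len(accession_idx)
        return np.ones(n)


def generate_truth(
    n_proteins: int = 5000,
    n_pathways: int = 186,
    frac_de: float = 0.1,
    effect_range: tuple[float, float] = (1.15, 2.0),
    frac_mito: float = 0.12,
    sigma: float = 0.02,
    dropout: float = 0.05,
    treatments: Sequence[str] = DEFAULT_TREATMENTS,
    control: str = DEFAULT_CONTROL,
    plex_scale: dict[str, float] | None = None,
    pathway_size_range: tuple[int, int] = (25, 80),
    reciprocal_prob: float = 0.5,
    seed: int = 20200707,
) -> GroundTruth:
    """Draw a reproducible ground-truth object.

    ``frac_de`` of the proteins are perturbed per treatment (drawn without
    replacement, independently per treatment), with ratios uniform in
    ``effect_range`` and flipped to their reciprocal with probability
    ``reciprocal_prob`` (up/down mix).  ``frac_de = 0`` yields a null
    dataset with no perturbed proteins and no planted pathways.
    """
    if not 0 <= frac_de < 1:
        raise ValueError(f"frac_de must be in [0, 1), got {frac_de}")
    n_de = int(round(frac_de * n_proteins))
    if frac_de > 0 and n_de < 1:
        raise ValueError(
            f"frac_de={frac_de} and n_proteins={n_proteins} give no DE protein"
        )
    lo, hi = effect_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid effect_range {effect_range}")
    if frac_de > 0 and lo <= 1.0 <= hi:
        raise ValueError("effect_range must exclude a neighborhood of 1")

    rng = np.random.default_rng([seed, 1])
    accessions = [f"SYNP{i:05d}" for i in range(n_proteins)]
    baseline = 10 ** rng.uniform(5, 7, n_proteins)

    effects = pd.DataFrame(
        1.0, index=pd.Index(accessions, name="accession"), columns=list(treatments)
    )
    de_sets: dict[str, set[str]] = {}
    for t in treatments:
        if n_de == 0:
            de_sets[t] = set()
            continue
        idx = rng.choice(n_proteins, size=n_de, replace=False)
        ratios = rng.uniform(lo, hi, n_de)
        flip = rng.random(n_de) < reciprocal_prob
        ratios = np.where(flip, 1.0 / ratios, ratios)
        effects.iloc[idx, effects.columns.get_loc(t)] = ratios
        de_sets[t] = {accessions[i] for i in idx}

    n_mito = int(round(frac_mito * n_proteins))
    mito_idx = rng.choice(n_proteins, size=n_mito, replace=False)
    mito = {accessions[i] for i in mito_idx}
    classes = {
        accessions[i]: FUNCTIONAL_CLASSES[c]
        for i, c in zip(mito_idx, rng.integers(0, len(FUNCTIONAL_CLASSES), n_mito))
    }
    localization = {
        a: (dio.MITOCHONDRIAL if a in mito else dio.NON_MITOCHONDRIAL)
        for a in accessions
    }

    # pathway universe: measurable proteins plus never-detected annotations
    phantom_pool = [f"SYNU{i:05d}" for i in range(n_proteins)]
    pathways: list[PathwayAnnotation] = []
    planted: dict[str, str] = {}
    plantable = list(treatments) if n_de > 0 else []
    for j in range(n_pathways):
        size = int(rng.integers(pathway_size_range[0], pathway_size_range[1] + 1))
        n_phantom = int(round(PHANTOM_FRACTION * size))
        n_real = max(size - n_phantom, 1)
        name = f"PW{j + 1:03d}"
        if j < len(plantable):
            t = plantable[j]
            planted[t] = name
            n_from_de = min(int(round(PLANTED_DE_FRACTION * n_real)), n_de)
            de_list = sorted(de_sets[t])
            members_de = list(
                rng.choice(de_list, size=n_from_de, replace=False)
            )
            non_de = sorted(set(accessions) - de_sets[t])
            members_bg = list(
                rng.choice(non_de, size=n_real - n_from_de, replace=False)
            )
            real_members = members_de + members_bg
        else:
            real_members = list(
                rng.choice(accessions, size=n_real, replace=False)
            )
        phantoms = list(rng.choice(phantom_pool, size=n_phantom, replace=False))
        pathways.append(
            PathwayAnnotation(name, frozenset(real_members + phantoms), "synthetic")
        )

    params = {
        "n_proteins": n_proteins,
        "n_pathways": n_pathways,
        "frac_de": frac_de,
        "effect_range": list(effect_range),
        "frac_mito": frac_mito,
        "sigma": sigma,
        "dropout": dropout,
        "treatments": list(treatments),
        "control": control,
        "pathway_size_range": list(pathway_size_range),
        "reciprocal_prob": reciprocal_prob,
        "planted_de_fraction": PLANTED_DE_FRACTION,
        "phantom_fraction": PHANTOM_FRACTION,
    }
    return GroundTruth(
        seed=seed,
        accessions=accessions,
        baseline=baseline,
        effects=effects,
        de_sets=de_sets,
        pathways=pathways,
        planted=planted,
        mito=mito,
        classes=classes,
        localization=localization,
        plex_scale=plex_scale or {},
        sigma=sigma,
        dropout=dropout,
        control=control,
        params=params,
    )


def paper_design() -> list[PlexDesign]:
    """Two 11-plex sets: set 1 = FCCP/dinoterb/picoxystrobin triplicates,
    set 2 = pinacyanol/triclocarban/DMSO triplicates, two pooled-reference
    channels per set."""

    def plex(plex_id: str, groups: Sequence[str]) -> PlexDesign:
        channels = []
        i = 0
        for g in groups:
            for rep in (1, 2, 3):
                channels.append(
                    Channel(TMT11_LABELS[i], f"{g}_r{rep}", g, rep)
                )
                i += 1
        for rep in (1, 2):
            channels.append(
                Channel(TMT11_LABELS[i], f"{plex_id}_pool{rep}", dio.POOLED_REF, rep)
            )
            i += 1
        return PlexDesign(plex_id, channels)

    return [
        plex("set1", ("FCCP", "dinoterb", "picoxystrobin")),
        plex("set2", ("pinacyanol", "triclocarban", "DMSO")),
    ]


def minimal_design() -> list[PlexDesign]:
    """One 6-channel plex: two groups in duplicate plus two pooled refs."""
    channels = [
        Channel("126", "treatA_r1", "treatA", 1),
        Channel("127N", "treatA_r2", "treatA", 2),
        Channel("127C", "DMSO_r1", "DMSO", 1),
        Channel("128N", "DMSO_r2", "DMSO", 2),
        Channel("128C", "mini_pool1", dio.POOLED_REF, 1),
        Channel("129N", "mini_pool2", dio.POOLED_REF, 2),
    ]
    return [PlexDesign("mini", channels)]


def simulate_plexes(
    truth: GroundTruth, designs: Sequence[PlexDesign]
) -> list[ReporterIntensityTable]:
    """Simulate integer reporter-intensity tables for the given designs.

    Per channel: intensity = baseline · effect(group) · plex_scale ·
    exp(N(0, σ²)).  Pooled-reference channels carry the equal-weight mean
    of all sample signals (before plex scaling) with their own measurement
    noise.  Per plex, each protein is dropped entirely with probability
    ``dropout`` (undetected in that run).
    """
    rng = np.random.default_rng([truth.seed, 2])
    n = len(truth.accessions)
    idx = np.arange(n)

    all_samples = [ch for d in designs for ch in d.sample_channels]
    pooled_mu = np.zeros(n)
    for ch in all_samples:
        pooled_mu += truth.baseline * truth.effect(idx, ch.group)
    pooled_mu /= len(all_samples)

    tables = []
    for d in designs:
        scale = truth.plex_scale.get(d.plex_id, 1.0)
        keep = rng.random(n) >= truth.dropout
        cols = {}
        for ch in d.channels:
            mu = (
                pooled_mu
                if ch.is_reference
                else truth.baseline * truth.effect(idx, ch.group)
            )
            noise = (
                np.exp(rng.normal(0.0, truth.sigma, n)) if truth.sigma > 0 else 1.0
            )
            cols[ch.channel] = np.rint(mu * scale * noise)
        data = pd.DataFrame(cols, index=pd.Index(truth.accessions, name="accession"))
        data = data.loc[keep]
        annotations = pd.DataFrame(
            {
                "gene_symbol": [a.replace("SYNP", "SYNG") for a in data.index],
                "localization": [truth.localization[a] for a in data.index],
                "psm_count": rng.integers(2, 60, int(keep.sum())),
            },
            index=data.index,
        )
        table = ReporterIntensityTable(d.plex_id, data, annotations)
        table.validate(d)
        tables.append(table)
    return tables


def write_fixture_set(
    truth: GroundTruth,
    tables: Sequence[ReporterIntensityTable],
    designs: Sequence[PlexDesign],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a complete fixture: design, per-plex intensity tables, GMT,
    localization and functional-class maps, and the ground-truth JSON.

    All files parse cleanly through the design/IO layer; the truth JSON
    carries everything needed to score recovery (true effects, DE sets,
    planted pathways).  Re-running with the same seed reproduces every
    file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["design"] = out / "design.tsv"
    dio.write_design(designs, paths["design"])
    for table in tables:
        p = out / f"intensities_{table.plex_id}.tsv"
        dio.write_intensity_table(table, p)
        paths[f"intensities_{table.plex_id}"] = p
    paths["gmt"] = out / "pathways.gmt"
    dio.write_gmt(truth.pathways, paths["gmt"])
    paths["localization"] = out / "localization.tsv"
    dio.write_two_column(
        truth.localization, paths["localization"], "accession", "localization"
    )
    paths["classes"] = out / "classes.tsv"
    dio.write_two_column(
        truth.classes, paths["classes"], "accession", "functional_class"
    )

    effects_sparse = {
        t: {
            a: float(truth.effects.loc[a, t])
            for a in sorted(truth.de_sets[t])
        }
        for t in truth.treatments
    }
    truth_doc = {
        "seed": truth.seed,
        "params": truth.params,
        "control": truth.control,
        "plex_scale": truth.plex_scale,
        "de_sets": {t: sorted(s) for t, s in truth.de_sets.items()},
        "effects": effects_sparse,
        "planted": truth.planted,
        "mito": sorted(truth.mito),
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# presets


def preset(name: str, seed: int | None = None, **overrides):
    """Build (truth, tables, designs) for a named preset.

    ``paper``   — two 11-plex sets, 5,000 proteins, 10% perturbed per
                  treatment at ratios 1.15–2, σ = 0.02, 5% per-plex
                  dropout, mild plex batch factor.
    ``null``    — same design, 1,000 proteins, no true effects, no dropout.
    ``minimal`` — one 6-channel plex, 3 proteins, noiseless, one planted
                  two-fold effect; every summary count is hand-checkable.
    """
    if name == "paper":
        params = dict(seed=20200707, plex_scale={"set1": 1.0, "set2": 1.25})
        params.update(overrides)
        if seed is not None:
            params["seed"] = seed
        truth = generate_truth(**params)
        designs = paper_design()
    elif name == "null":
        params = dict(
            n_proteins=1000,
            n_pathways=50,
            frac_de=0.0,
            dropout=0.0,
            seed=20200707,
            plex_scale={"set1": 1.0, "set2": 1.25},
        )
        params.update(overrides)
        if seed is not None:
            params["seed"] = seed
        truth = generate_truth(**params)
        designs = paper_design()
    elif name == "minimal":
        params = dict(
            n_proteins=3,
            n_pathways=1,
            frac_de=1 / 3,
            effect_range=(2.0, 2.0),
            reciprocal_prob=0.0,
            frac_mito=1 / 3,
            sigma=0.01,
            dropout=0.0,
            treatments=("treatA",),
            pathway_size_range=(3, 3),
            seed=20200707,
        )
        params.update(overrides)
        if seed is not None:
            params["seed"] = seed
        truth = generate_truth(**params)
        designs = minimal_design()
    else:
        raise ValueError(f"unknown preset {name!r}; one of paper, null, minimal")
    tables = simulate_plexes(truth, designs)
    return truth, tables, designs
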
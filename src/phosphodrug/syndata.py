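"""Seeded generator of synthetic panel data with planted ground truth.

Emulates the statistical regime the analysis assumes: log10 LFQ-like
intensities with intensity-dependent (MNAR) missingness, tissue-group
covariance, planted single-cell-line outliers, planted pathway/kinase
activity shifts, correlated feature modules (one of them differential in
a binary MSI-like phenotype), linear drug markers, and drug clusters
sharing marker sets.

Design notes
------------
* Latent factors (module and marker-cluster drivers) are uniform on
  [-sqrt(3), sqrt(3)] — unit variance but bounded, so correlated blocks
  never masquerade as single-cell-line outliers.
* Every output block draws from its own child RNG stream of the master
  seed, so adding outputs never perturbs existing ones.
* Planted marker features are exempt from MNAR masking so the planted
  drug-feature relationships survive in the emitted matrices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigError,
    DrugResponseMatrix,
    IntensityMatrix,
    PsiteAnnotation,
    SetCollection,
)
from . import core_io

_SQRT3 = np.sqrt(3.0)


@dataclass
class SimConfig:
    """Configuration of the synthetic panel generator.

    All intensity-scale fields are in log10 units.
    """

    n_cell_lines: int = 60
    n_proteins: int = 300
    n_psites: int = 300
    n_tissue_groups: int = 4
    tissue_shift_sd: float = 0.05
    noise_sd: float = 0.05
    baseline_mean: float = 7.0
    baseline_sd: float = 0.5
    missing_midpoint: float = 6.3
    missing_steepness: float = 3.0
    n_pathways: int = 8
    pathway_size: int = 10
    n_kinases: int = 8
    substrates_per_kinase: int = 5
    activity_shift: float = 0.4
    n_outliers: int = 5
    outlier_shift: float = 1.0
    n_drugs: int = 20
    n_planted_markers_per_drug: int = 5
    marker_effect: float = 1.0
    n_drug_clusters: int = 2
    phenotype_fraction: float = 0.4
    n_differential_features: int = 30
    differential_shift: float = 0.25
    seed: int = 0
    # secondary structure knobs
    n_active_kinases: int = 3
    n_extra_modules: int = 1
    module_size: int = 30
    module_correlation: float = 0.9
    common_marker_effect: float = 0.5
    response_noise_sd: float = 0.25
    own_sites_per_kinase: int = 2

    def validate(self) -> None:
        counts = [
            "n_cell_lines", "n_proteins", "n_psites", "n_tissue_groups",
            "n_pathways", "pathway_size", "n_kinases", "substrates_per_kinase",
            "n_outliers", "n_drugs", "n_planted_markers_per_drug",
            "n_drug_clusters", "n_differential_features",
        ]
        for name in counts:
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 < self.phenotype_fraction < 1.0):
            raise ConfigError(
                f"phenotype_fraction must be in (0,1), got {self.phenotype_fraction}"
            )
        if not (0.0 <= self.module_correlation < 1.0):
            raise ConfigError(
                f"module_correlation must be in [0,1), got {self.module_correlation}"
            )
        if self.pathway_size > self.n_proteins:
            raise ConfigError("pathway_size exceeds n_proteins")
        if self.substrates_per_kinase > self.n_psites:
            raise ConfigError("substrates_per_kinase exceeds n_psites")
        if self.n_active_kinases > min(self.n_kinases, self.n_cell_lines):
            raise ConfigError("n_active_kinases exceeds n_kinases or n_cell_lines")
        if self.n_drug_clusters > self.n_drugs:
            raise ConfigError("n_drug_clusters exceeds n_drugs")
        layout = _Layout.plan(self)  # raises ConfigError when space runs out
        del layout


@dataclass
class GroundTruth:
    """Index of every planted structure in a generated dataset."""

    outlier_positions: list[tuple[str, str]]
    active_kinase_per_group: dict[str, list[str]]
    marker_map: dict[str, list[tuple[str, int]]]
    drug_cluster_labels: dict[str, int]
    differential_features: list[tuple[str, str]]
    module_labels: dict[str, int]
    common_marker: str = ""
    active_pathway_cells: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        raw["outlier_positions"] = [tuple(t) for t in raw["outlier_positions"]]
        raw["marker_map"] = {
            d: [(f, int(s)) for f, s in lst] for d, lst in raw["marker_map"].items()
        }
        raw["differential_features"] = [tuple(t) for t in raw["differential_features"]]
        return cls(**raw)


@dataclass
class _Layout:
    """Deterministic allocation of feature index ranges to planted roles."""

    pathway_members: dict[str, list[int]]          # protein indices
    module_proteins: dict[int, list[int]]          # module id -> protein idx
    module_psites: dict[int, list[int]]            # module id -> psite idx
    kinase_proteins: list[int]
    common_marker: int
    cluster_markers: dict[int, list[int]]          # cluster -> protein idx
    outlier_proteins: list[int]
    kinase_own_sites: dict[int, list[int]]         # kinase ordinal -> psite idx
    kinase_substrates: dict[int, list[int]]        # kinase ordinal -> psite idx

    @classmethod
    def plan(cls, cfg: SimConfig) -> "_Layout":
        p = 0  # protein cursor

        def take_p(n: int, what: str) -> list[int]:
            nonlocal p
            if p + n > cfg.n_proteins:
                raise ConfigError(
                    f"n_proteins={cfg.n_proteins} too small for planted structure"
                    f" (ran out while allocating {what})"
                )
            out = list(range(p, p + n))
            p += n
            return out

        # ordinary pathways consume blocks; the last pathway is rebuilt from
        # the differential module below so set<->module enrichment is planted
        pathway_members = {
            f"PATH{k:02d}": take_p(cfg.pathway_size, f"pathway {k}")
            for k in range(cfg.n_pathways - 1)
        }

        m1p = cfg.n_differential_features - cfg.n_differential_features // 2
        m1s = cfg.n_differential_features // 2
        if m1s < 1:
            m1s = 0
        module_proteins = {1: take_p(m1p, "differential module")}
        module_psites = {1: []}
        for m in range(2, 2 + cfg.n_extra_modules):
            mp = cfg.module_size - cfg.module_size // 2
            module_proteins[m] = take_p(mp, f"module {m}")
            module_psites[m] = []

        diff_name = f"PATH{cfg.n_pathways - 1:02d}"
        pathway_members[diff_name] = module_proteins[1][: cfg.pathway_size]

        kinase_proteins = take_p(cfg.n_kinases, "kinases")
        common_marker = take_p(1, "common marker")[0]
        cluster_markers = {
            c: take_p(cfg.n_planted_markers_per_drug, f"drug cluster {c}")
            for c in range(cfg.n_drug_clusters)
        }
        outlier_proteins = take_p(cfg.n_outliers, "outliers")

        # p-site allocation
        s = 0

        def take_s(n: int, what: str) -> list[int]:
            nonlocal s
            if s + n > cfg.n_psites:
                raise ConfigError(
                    f"n_psites={cfg.n_psites} too small for planted structure"
                    f" (ran out while allocating {what})"
                )
            out = list(range(s, s + n))
            s += n
            return out

        module_psites[1] = take_s(m1s, "differential module sites")
        for m in range(2, 2 + cfg.n_extra_modules):
            module_psites[m] = take_s(cfg.module_size // 2, f"module {m} sites")
        kinase_own_sites = {
            k: take_s(cfg.own_sites_per_kinase, f"kinase {k} own sites")
            for k in range(cfg.n_kinases)
        }
        kinase_substrates = {
            k: take_s(cfg.substrates_per_kinase, f"kinase {k} substrates")
            for k in range(cfg.n_kinases)
        }
        return cls(
            pathway_members=pathway_members,
            module_proteins=module_proteins,
            module_psites=module_psites,
            kinase_proteins=kinase_proteins,
            common_marker=common_marker,
            cluster_markers=cluster_markers,
            outlier_proteins=outlier_proteins,
            kinase_own_sites=kinase_own_sites,
            kinase_substrates=kinase_substrates,
        )


def _uniform_latent(rng: np.random.Generator, size) -> np.ndarray:
    """Unit-variance bounded latent factor."""
    return rng.uniform(-_SQRT3, _SQRT3, size=size)


def generate_dataset(config: SimConfig):
    """Generate the full synthetic dataset.

    Returns
    -------
    (protein, psite, pathways, kinase_substrates, drugs, phenotype,
    annotation, truth) where `drugs` is sAUC-like (higher = more
    sensitive), `phenotype` is a 0/1 Series over cell lines, `annotation`
    is the list of PsiteAnnotation records and `truth` is a GroundTruth.
    """
    config.validate()
    cfg = config
    layout = _Layout.plan(cfg)

    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            [
                "baseline", "tissue", "noise", "latents", "phenotype",
                "markers", "drugs", "outliers", "missing", "kinases", "sites",
            ],
            np.random.SeedSequence(cfg.seed).spawn(11),
        )
    }

    n_c = cfg.n_cell_lines
    cells = [f"CL{i + 1:03d}" for i in range(n_c)]
    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    group_of_cell = np.arange(n_c) % cfg.n_tissue_groups

    # ---- p-site identities -------------------------------------------------
    site_rng = streams["sites"]
    residues = np.array(["S", "T", "Y"])
    psite_ids: list[str] = [""] * cfg.n_psites
    annotation: list[PsiteAnnotation | None] = [None] * cfg.n_psites
    own_site_idx = {i for lst in layout.kinase_own_sites.values() for i in lst}

    host_of_site: dict[int, int] = {}
    for k, sites in layout.kinase_own_sites.items():
        for i in sites:
            host_of_site[i] = layout.kinase_proteins[k]
    # all remaining sites sit on non-kinase host proteins
    plain_hosts = [
        i for i in range(cfg.n_proteins)
        if i not in set(layout.kinase_proteins)
    ]
    for i in range(cfg.n_psites):
        if i not in host_of_site:
            host_of_site[i] = plain_hosts[int(site_rng.integers(len(plain_hosts)))]

    used_positions: dict[int, set[int]] = {}
    for i in range(cfg.n_psites):
        host = host_of_site[i]
        res = str(residues[int(site_rng.integers(3))])
        pos = int(site_rng.integers(1, 2000))
        taken = used_positions.setdefault(host, set())
        while pos in taken:
            pos = int(site_rng.integers(1, 2000))
        taken.add(pos)
        pid = f"{proteins[host]}_p{res}{pos}"
        psite_ids[i] = pid
        if i in own_site_idx:
            # first own site per kinase is annotated activating, the second
            # inhibitory on odd kinases to exercise the regulatory screen
            k = next(k for k, lst in layout.kinase_own_sites.items() if i in lst)
            first = layout.kinase_own_sites[k][0] == i
            reg = "activating" if first else ("inhibitory" if k % 2 else "unknown")
        else:
            reg = "unknown"
        annotation[i] = PsiteAnnotation(pid, proteins[host], res, pos, reg)
    annotation_list: list[PsiteAnnotation] = [a for a in annotation if a is not None]

    # ---- base signal -------------------------------------------------------
    n_feat = cfg.n_proteins + cfg.n_psites
    baseline = streams["baseline"].normal(cfg.baseline_mean, cfg.baseline_sd, n_feat)
    # planted module members are kept above the mean intensity (folded
    # normal) so MNAR masking cannot push them under the observation filter
    module_rows = [
        i for m in layout.module_proteins for i in layout.module_proteins[m]
    ] + [
        cfg.n_proteins + i for m in layout.module_psites for i in layout.module_psites[m]
    ]
    baseline[module_rows] = cfg.baseline_mean + np.abs(
        baseline[module_rows] - cfg.baseline_mean
    )
    tissue = streams["tissue"].normal(
        0.0, cfg.tissue_shift_sd, size=(n_feat, cfg.n_tissue_groups)
    )
    true = baseline[:, None] + tissue[:, group_of_cell]
    true += streams["noise"].normal(0.0, cfg.noise_sd, size=(n_feat, n_c))

    def fid(kind: str, idx: int) -> str:
        return proteins[idx] if kind == "protein" else psite_ids[idx]

    def row(kind: str, idx: int) -> int:
        return idx if kind == "protein" else cfg.n_proteins + idx

    # ---- phenotype + differential module ----------------------------------
    n_pos = max(1, round(cfg.phenotype_fraction * n_c))
    pos_cells = np.sort(streams["phenotype"].choice(n_c, size=n_pos, replace=False))
    phenotype = pd.Series(0, index=cells, name="phenotype", dtype=int)
    phenotype.iloc[pos_cells] = 1

    resid_var = cfg.noise_sd**2 + cfg.tissue_shift_sd**2
    module_labels: dict[str, int] = {}
    lat_rng = streams["latents"]
    rho = cfg.module_correlation
    for m in sorted(layout.module_proteins):
        members = [("protein", i) for i in layout.module_proteins[m]] + [
            ("p-site", i) for i in layout.module_psites[m]
        ]
        if rho > 0:
            shift_var = (
                cfg.differential_shift**2
                * cfg.phenotype_fraction
                * (1 - cfg.phenotype_fraction)
                if m == 1
                else 0.0
            )
            # shared variance needed for pairwise correlation ~= rho
            lam2 = max(rho / (1 - rho) * resid_var - shift_var, 0.0)
            lam = np.sqrt(lam2)
            z = _uniform_latent(lat_rng, n_c)
            for kind, i in members:
                true[row(kind, i)] += lam * z
        for kind, i in members:
            module_labels[fid(kind, i)] = m
    differential_features: list[tuple[str, str]] = []
    if cfg.differential_shift != 0.0:
        for kind, i in [("protein", i) for i in layout.module_proteins[1]] + [
            ("p-site", i) for i in layout.module_psites[1]
        ]:
            true[row(kind, i), pos_cells] += cfg.differential_shift
            differential_features.append((fid(kind, i), "up-in-positive"))
    else:
        differential_features = []

    # ---- pathway + kinase activity shifts ----------------------------------
    active_pathway_cells: dict[str, list[str]] = {}
    first_path = "PATH00"
    g0_cells = np.flatnonzero(group_of_cell == 0)
    for i in layout.pathway_members[first_path]:
        true[i, g0_cells] += cfg.activity_shift
    active_pathway_cells[first_path] = [cells[c] for c in g0_cells]

    kin_rng = streams["kinases"]
    active_cells = kin_rng.choice(n_c, size=cfg.n_active_kinases, replace=False)
    active_kinase_per_group: dict[str, list[str]] = {}
    for k in range(cfg.n_active_kinases):
        c = int(active_cells[k])
        kin_prot = layout.kinase_proteins[k]
        true[kin_prot, c] += cfg.activity_shift
        for i in layout.kinase_own_sites[k] + layout.kinase_substrates[k]:
            true[row("p-site", i), c] += cfg.activity_shift
        active_kinase_per_group[proteins[kin_prot]] = [cells[c]]

    # ---- drug markers ------------------------------------------------------
    mark_rng = streams["markers"]
    cluster_latent = {
        c: _uniform_latent(mark_rng, n_c) for c in range(cfg.n_drug_clusters)
    }
    lam_marker = 3.0 * np.sqrt(resid_var)  # corr(marker, latent) ~= 0.95
    marker_signs: dict[int, list[int]] = {}
    for c, feats in layout.cluster_markers.items():
        signs = [1] + [int(s) for s in mark_rng.choice([-1, 1], size=len(feats) - 1)]
        marker_signs[c] = signs
        for i, s in zip(feats, signs):
            true[i] += lam_marker * s * cluster_latent[c]

    # ---- outliers (injected AFTER group/module/marker structure) ----------
    out_rng = streams["outliers"]
    outlier_cells = out_rng.integers(0, n_c, size=cfg.n_outliers)
    outlier_positions: list[tuple[str, str]] = []
    for j, i in enumerate(layout.outlier_proteins):
        c = int(outlier_cells[j])
        others = np.delete(true[i], c)
        margin = float(out_rng.uniform(0.02, 0.3))
        true[i, c] = np.median(others) + cfg.outlier_shift + margin
        outlier_positions.append((proteins[i], cells[c]))

    # ---- drug response -----------------------------------------------------
    drug_rng = streams["drugs"]
    drug_ids = [f"DRUG{d + 1:02d}" for d in range(cfg.n_drugs)]
    cluster_of_drug = {d: d % cfg.n_drug_clusters for d in range(cfg.n_drugs)}
    feat_mean = true.mean(axis=1, keepdims=True)
    feat_sd = true.std(axis=1, keepdims=True)
    feat_sd[feat_sd == 0] = 1.0
    z_all = (true - feat_mean) / feat_sd
    z_common = z_all[layout.common_marker]

    marker_map: dict[str, list[tuple[str, int]]] = {}
    sens = np.empty((cfg.n_drugs, n_c))
    for d, drug in enumerate(drug_ids):
        c = cluster_of_drug[d]
        feats = layout.cluster_markers[c]
        signs = marker_signs[c]
        signed_z = np.mean([s * z_all[i] for i, s in zip(feats, signs)], axis=0)
        intercept = float(drug_rng.normal(0.0, 0.5))
        sens[d] = (
            intercept
            + cfg.marker_effect * signed_z
            + cfg.common_marker_effect * cfg.marker_effect * z_common
            + drug_rng.normal(0.0, cfg.response_noise_sd, n_c)
        )
        marker_map[drug] = [
            (proteins[i], s) for i, s in zip(feats, signs)
        ] + [(proteins[layout.common_marker], 1)]

    drugs = DrugResponseMatrix(
        pd.DataFrame(sens, index=drug_ids, columns=cells), higher_is_sensitive=True
    )

    # ---- MNAR missingness --------------------------------------------------
    miss_rng = streams["missing"]
    with np.errstate(over="ignore"):
        p_missing = 1.0 / (
            1.0 + np.exp(cfg.missing_steepness * (true - cfg.missing_midpoint))
        )
    mask = miss_rng.uniform(size=true.shape) < p_missing
    # planted outliers and marker features stay observed (see module notes)
    for j, i in enumerate(layout.outlier_proteins):
        mask[i, int(outlier_cells[j])] = False
    keep_rows = [layout.common_marker] + [
        i for feats in layout.cluster_markers.values() for i in feats
    ]
    mask[keep_rows, :] = False
    observed = true.copy()
    observed[mask] = np.nan

    protein_mat = IntensityMatrix(
        pd.DataFrame(observed[: cfg.n_proteins], index=proteins, columns=cells),
        "protein",
    )
    psite_mat = IntensityMatrix(
        pd.DataFrame(observed[cfg.n_proteins :], index=psite_ids, columns=cells),
        "p-site",
    )

    pathways = SetCollection(
        {name: [proteins[i] for i in members]
         for name, members in layout.pathway_members.items()},
        descriptions={name: "synthetic pathway" for name in layout.pathway_members},
    )
    kin_sets = SetCollection(
        {
            proteins[layout.kinase_proteins[k]]: [
                psite_ids[i] for i in layout.kinase_substrates[k]
            ]
            for k in range(cfg.n_kinases)
        },
        descriptions={
            proteins[layout.kinase_proteins[k]]: "synthetic kinase substrates"
            for k in range(cfg.n_kinases)
        },
    )

    truth = GroundTruth(
        outlier_positions=outlier_positions,
        active_kinase_per_group=active_kinase_per_group,
        marker_map=marker_map,
        drug_cluster_labels={drug_ids[d]: cluster_of_drug[d] for d in range(cfg.n_drugs)},
        differential_features=differential_features,
        module_labels=module_labels,
        common_marker=proteins[layout.common_marker],
        active_pathway_cells=active_pathway_cells,
    )
    return protein_mat, psite_mat, pathways, kin_sets, drugs, phenotype, annotation_list, truth


def write_dataset(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate a dataset and write all text artifacts into `out_dir`.

    Drug sensitivities are emitted in both conventions: drugs.tsv is
    sAUC-like (higher = more sensitive) and drugs_gi50.tsv is its
    GI50-like negation (lower = more sensitive).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protein, psite, pathways, kin_sets, drugs, phenotype, annotation, truth = (
        generate_dataset(config)
    )
    paths = {
        "protein": out / "protein.tsv",
        "psites": out / "psites.tsv",
        "pathways": out / "pathways.gmt",
        "kinase_substrates": out / "kinase_substrates.gmt",
        "annotation": out / "annotation.tsv",
        "drugs": out / "drugs.tsv",
        "drugs_gi50": out / "drugs_gi50.tsv",
        "phenotype": out / "phenotype.tsv",
        "truth": out / "truth.json",
    }
    core_io.write_intensity_tsv(protein, paths["protein"])
    core_io.write_intensity_tsv(psite, paths["psites"])
    core_io.write_gmt(pathways, paths["pathways"])
    core_io.write_gmt(kin_sets, paths["kinase_substrates"])
    core_io.write_psite_annotation(annotation, paths["annotation"])
    core_io.write_drug_tsv(drugs, paths["drugs"])
    gi50 = DrugResponseMatrix(-drugs.values, higher_is_sensitive=False)
    core_io.write_drug_tsv(gi50, paths["drugs_gi50"])
    core_io.write_phenotype_tsv(phenotype, paths["phenotype"])
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths
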
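"""Synthetic trees, trait tables and toy body models.

Generates data with the statistical and geometric structure the analysis
assumes, so every pipeline stage can run and be validated without any real
measurement table:

* pure-birth (Yule) ultrametric trees;
* Brownian-motion trait evolution along a tree;
* clade trait tables in which log10(stylopodial index) evolves by Brownian
  motion and log10(relative CoM) follows a clade-specific log-linear
  relation with either i.i.d. Gaussian residuals (the OLS regime) or
  Brownian residuals (the PGLS regime);
* primitive-solid body models (boxes, cylinders, icospheres) with
  analytically known mass and centre of mass;
* :func:`make_study_fixture`, a complete miniature study whose default
  clade parameters echo the published extant equations — slopes
  0.866 / 1.375 / 0.652, intercepts -0.294 / -0.374 / -0.245 and residual
  SDs 0.02 / 0.06 / 0.075 for the mammal, non-avian sauropsid and bird
  analogues — with per-clade sample sizes 10 / 16 / 31.

All generators are deterministic under a seed; per-stage substreams are
derived with :class:`numpy.random.SeedSequence` so stages stay independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .indices import StylopodMeasurements, measurements_frame
from .mass_properties import BodyModel, SegmentMesh
from .phylo import PhyloTree, parse_newick

__all__ = [
    "CladeParams",
    "DEFAULT_CLADES",
    "simulate_tree",
    "simulate_brownian",
    "simulate_clade_traits",
    "synth_body",
    "SyntheticBody",
    "StudyFixture",
    "make_study_fixture",
]


# ---------------------------------------------------------------------------
# Trees


def _yule_newick(labels: list[str], birth_rate: float, rng: np.random.Generator) -> tuple[str, float]:
    """Pure-birth tree over the given tip labels; returns (newick sans ';', depth)."""
    n = len(labels)
    # Node bookkeeping: each active lineage records its birth time and the
    # newick fragments of its resolved descendants (None while pendant).
    next_id = 0
    birth: dict[int, float] = {next_id: 0.0, next_id + 1: 0.0}
    children: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        children[parent] = (next_id, next_id + 1)
        for c in (next_id, next_id + 1):
            birth[c] = t
            children[c] = None
            active.append(c)
        next_id += 2
    t += rng.exponential(1.0 / (birth_rate * n))  # extend pendant edges to present

    label_iter = iter(labels)

    def render(node: int) -> str:
        """Newick fragment for a lineage born at birth[node]; its edge length
        runs from its birth to the birth of its children (or the present)."""
        if children[node] is None:
            return f"{next(label_iter)}:{t - birth[node]:.10g}"
        a, b = children[node]
        return f"({render(a)},{render(b)}):{birth[a] - birth[node]:.10g}"

    return f"({render(0)},{render(1)})", t


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0) -> PhyloTree:
    """Ultrametric pure-birth tree with ``n`` tips, labelled t1..tn."""
    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    newick, _ = _yule_newick([f"t{i + 1}" for i in range(n)], birth_rate, rng)
    return parse_newick(newick + ";")


def simulate_brownian(
    tree: PhyloTree,
    rate: float,
    seed: int | np.random.Generator = 0,
    root_value: float = 0.0,
    return_nodes: bool = False,
):
    """Brownian trait values at the tips (optionally all nodes) of a tree.

    Each branch adds an independent Normal(0, sqrt(rate * length)) step.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    nodes: dict[str, float] = {}
    for node in tree._tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            value = root_value
        else:
            value = values[id(parent)] + rng.normal(0.0, np.sqrt(rate * node.edge.length))
        values[id(node)] = value
        if node.is_leaf():
            tips[node.stylocom_id] = value
        else:
            nodes[node.stylocom_id] = value
    return (tips, nodes) if return_nodes else tips


# ---------------------------------------------------------------------------
# Clade trait tables


@dataclass(frozen=True)
class CladeParams:
    """Generative parameters for one clade's index-CoM relation."""

    clade: str
    n_tips: int
    slope: float
    intercept: float
    residual_sd: float  # log10 space
    predictor: str = "C_index"  # which index carries the relation
    index_log_mean: float = 0.0  # root state of log10(index)
    index_bm_rate: float = 0.02  # Brownian rate of log10(index) per unit depth
    regime: str = "iid"  # "iid" (OLS) or "brownian" (PGLS) residuals
    birth_rate: float = 1.0
    n_ratites: int = 0


#: Defaults echoing the published mammal W1, non-avian sauropsid C and bird C
#: equations (slopes/intercepts) and their mean prediction errors (SDs), with
#: the study's per-clade sample sizes (10 mammals, 7 + 9 non-avian
#: sauropsids, 31 birds, of which several ratites).
DEFAULT_CLADES: tuple[CladeParams, ...] = (
    CladeParams("mammal", 10, 0.866, -0.294, 0.02, "W1_index", 0.0, 0.02),
    CladeParams("nonavian_sauropsid", 16, 1.375, -0.374, 0.06, "C_index", 0.0, 0.02),
    CladeParams("bird", 31, 0.652, -0.245, 0.075, "C_index", 0.0, 0.02, n_ratites=4),
)


def simulate_clade_traits(
    tree: PhyloTree,
    params: CladeParams,
    seed: int | np.random.Generator = 0,
    prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate (index, relative CoM) pairs for one clade on a tree.

    log10(index) evolves by Brownian motion; log10(relative CoM) is
    slope * log10(index) + intercept plus a residual that is either i.i.d.
    Gaussian or itself Brownian on the tree, per ``params.regime``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_index = simulate_brownian(tree, params.index_bm_rate, rng, params.index_log_mean)
    taxa = tree.tips
    lx = np.array([log_index[t] for t in taxa])
    if params.regime == "iid":
        resid = rng.normal(0.0, params.residual_sd, size=len(taxa))
    elif params.regime == "brownian":
        depth = max(tree.depths().values()) or 1.0
        bm = simulate_brownian(tree, params.residual_sd**2 / depth, rng, 0.0)
        resid = np.array([bm[t] for t in taxa])
    else:
        raise ValueError(f"unknown residual regime {params.regime!r}")
    ly = params.slope * lx + params.intercept + resid
    names = [f"{prefix}{i + 1}" if prefix else t for i, t in enumerate(taxa)]
    return pd.DataFrame(
        {
            "taxon": names,
            "tree_tip": taxa,
            "clade": params.clade,
            params.predictor: 10.0**lx,
            "relative_com": 10.0**ly,
        }
    )


# ---------------------------------------------------------------------------
# Toy body models


@dataclass
class SyntheticBody:
    """A primitive-solid body with analytic ground truth attached."""

    body: BodyModel
    true_mass: float
    true_volume: float
    true_com: np.ndarray
    true_relative_com: float


def _primitive(kind: str, spec: dict) -> tuple[trimesh.Trimesh, float, np.ndarray]:
    """Mesh plus analytic (volume, centroid) for one primitive segment."""
    center = np.asarray(spec.get("center", (0.0, 0.0, 0.0)), dtype=float)
    if kind == "box":
        extents = np.asarray(spec["extents"], dtype=float)
        mesh = trimesh.creation.box(extents=extents)
        volume = float(np.prod(extents))
    elif kind == "cylinder":
        r, h = float(spec["radius"]), float(spec["height"])
        sections = int(spec.get("sections", 128))
        mesh = trimesh.creation.cylinder(radius=r, height=h, sections=sections)
        # analytic volume of the *polygonal prism* actually meshed
        volume = 0.5 * sections * r**2 * np.sin(2 * np.pi / sections) * h
    elif kind == "ellipsoid":
        radii = np.asarray(spec["radii"], dtype=float)
        subdiv = int(spec.get("subdivisions", 4))
        mesh = trimesh.creation.icosphere(subdivisions=subdiv)
        mesh.apply_scale(radii)
        volume = float(mesh.volume)  # centroid is exact by symmetry
    elif kind == "sphere":
        r = float(spec["radius"])
        subdiv = int(spec.get("subdivisions", 4))
        mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=r)
        volume = float(mesh.volume)
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    mesh.apply_translation(center)
    return mesh, volume, center


def synth_body(recipe: dict) -> SyntheticBody:
    """Build a BodyModel from a primitive-segment recipe.

    Recipe::

        {"acetabulum": [0, 0, 0], "glenoid": [1, 0, 0],
         "ap_axis": [1, 0, 0],
         "segments": [{"kind": "box", "name": "torso", "density": 1.0,
                       "extents": [2, 1, 1], "center": [0.5, 0, 0]}, ...]}

    The analytic mass, centre of mass and relative CoM are attached as
    ground truth (sphere/ellipsoid segments use the meshed volume, whose
    centroid is exact by symmetry).
    """
    acet = np.asarray(recipe["acetabulum"], dtype=float)
    glen = np.asarray(recipe["glenoid"], dtype=float)
    if np.allclose(acet, glen):
        raise ValueError("acetabulum and glenoid landmarks coincide")
    segments, masses, moments, volumes = [], [], [], []
    for i, spec in enumerate(recipe["segments"]):
        kind = spec["kind"]
        density = float(spec.get("density", 1.0))
        mesh, volume, centroid = _primitive(kind, spec)
        segments.append(
            SegmentMesh(
                name=spec.get("name", f"{kind}{i}"),
                vertices=np.asarray(mesh.vertices, dtype=float),
                faces=np.asarray(mesh.faces, dtype=np.int64),
                density=density,
            )
        )
        masses.append(density * volume)
        volumes.append(volume)
        moments.append(density * volume * centroid)
    body = BodyModel(
        segments=segments,
        acetabulum=acet,
        glenoid=glen,
        ap_axis=np.asarray(recipe.get("ap_axis", [1.0, 0.0, 0.0]), dtype=float),
        name=recipe.get("taxon", "synthetic"),
    )
    mass = float(sum(masses))
    com = np.sum(moments, axis=0) / mass
    ap = body.ap_axis
    rel = float(np.dot(com - acet, ap) / np.dot(glen - acet, ap))
    return SyntheticBody(
        body=body,
        true_mass=mass,
        true_volume=float(sum(volumes)),
        true_com=com,
        true_relative_com=rel,
    )


# ---------------------------------------------------------------------------
# Complete miniature study


#: Clade-typical femoral dimensions (arbitrary mm) used to expand simulated
#: indices into raw measurement rows: humeral value = femoral value * index.
_FEMORAL_CONSTANTS = {
    "mammal": {"FC": 60.0, "FW1": 18.0, "FW2": 20.0, "FL": 180.0},
    "nonavian_sauropsid": {"FC": 40.0, "FW1": 12.0, "FW2": 13.0, "FL": 120.0},
    "bird": {"FC": 25.0, "FW1": 8.0, "FW2": 8.5, "FL": 90.0},
    "theropod": {"FC": 300.0, "FW1": 90.0, "FW2": 100.0, "FL": 1000.0},
    "sauropodomorph": {"FC": 600.0, "FW1": 180.0, "FW2": 200.0, "FL": 1500.0},
    "ornithischian": {"FC": 400.0, "FW1": 120.0, "FW2": 130.0, "FL": 1100.0},
}

_CLADE_PREFIX = {
    "mammal": "m",
    "nonavian_sauropsid": "s",
    "bird": "b",
    "theropod": "th",
    "sauropodomorph": "sa",
    "ornithischian": "or",
}


def _rows_from_traits(
    traits: pd.DataFrame,
    params: CladeParams,
    rng: np.random.Generator,
    ratite_taxa: set[str] = frozenset(),
) -> list[StylopodMeasurements]:
    """Expand simulated index/CoM pairs into full measurement rows.

    Femoral dimensions are clade-typical constants times a per-taxon size
    factor; the humeral counterpart of the simulated predictor equals the
    femoral value times the simulated index exactly, so the ratio
    round-trips.  The remaining indices track the simulated one with a
    small lognormal jitter (they are correlated proxies, not independent).
    """
    fem = _FEMORAL_CONSTANTS[params.clade]
    pred_pair = {"C_index": "HC", "W1_index": "HW1", "W2_index": "HW2", "L_index": "HL"}
    rows = []
    for _, rec in traits.iterrows():
        size = float(np.exp(rng.normal(0.0, 0.3)))
        index = float(rec[params.predictor])
        jitters = {h: float(np.exp(rng.normal(0.0, 0.03))) for h in ("HC", "HW1", "HW2", "HL")}
        jitters[pred_pair[params.predictor]] = 1.0
        f = {k: v * size for k, v in fem.items()}
        kwargs = {
            "FC": f["FC"],
            "FW1": f["FW1"],
            "FW2": f["FW2"],
            "FL": f["FL"],
            "HC": f["FC"] * index * jitters["HC"],
            "HW1": f["FW1"] * index * jitters["HW1"],
            "HW2": f["FW2"] * index * jitters["HW2"],
            "HL": f["FL"] * (0.8 + 0.2 * index) * jitters["HL"],
        }
        body_mass = float(25.0 * size**3 * np.exp(rng.normal(0.0, 0.1)))
        rows.append(
            StylopodMeasurements(
                taxon=rec["taxon"],
                clade=params.clade,
                body_mass=body_mass,
                relative_com=float(rec["relative_com"]),
                flags={"ratite"} if rec["taxon"] in ratite_taxa else set(),
                **kwargs,
            )
        )
    return rows


@dataclass
class StudyFixture:
    """A complete synthetic study bundle."""

    extant_rows: list[StylopodMeasurements]
    extant_frame: pd.DataFrame
    tree: PhyloTree
    tip_map: dict[str, str]  # taxon -> original simulated tip id
    fossil_rows: list[StylopodMeasurements]
    fossil_frame: pd.DataFrame
    fossil_tree: PhyloTree
    fossil_reference: dict[str, float]
    answer_key: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_measurement_csv(self.extant_rows, outdir / "extant_measurements.csv")
        _write_measurement_csv(self.fossil_rows, outdir / "fossil_measurements.csv")
        self.tree.write(outdir / "extant_tree.nwk")
        self.fossil_tree.write(outdir / "fossil_tree.nwk")
        pd.Series(self.fossil_reference, name="relative_com").rename_axis("taxon").to_csv(
            outdir / "fossil_reference.csv"
        )
        (outdir / "manifest.json").write_text(json.dumps(self.answer_key, indent=2) + "\n")


def _write_measurement_csv(rows: list[StylopodMeasurements], path: Path) -> None:
    df = measurements_frame(rows)[
        ["taxon", "clade", "HC", "FC", "HW1", "FW1", "HW2", "FW2", "HL", "FL",
         "body_mass", "relative_com", "ratite"]
    ].copy()
    df["notes"] = ""
    df.to_csv(path, index=False, float_format="%.10g")


def make_study_fixture(
    seed: int = 0,
    clades: tuple[CladeParams, ...] = DEFAULT_CLADES,
    n_fossils_per_clade: int = 8,
) -> StudyFixture:
    """Generate the default miniature study (see module docstring).

    Extant clades sit on one joint ultrametric tree (per-clade pure-birth
    subtrees grafted onto a common root); the taxa with the lowest simulated
    indices in the bird clade are flagged as ratite analogues (small
    forelimbs, posterior CoM).  Fossil clades get their own tree, indices in
    a realistic range, and reference relative CoM values equal to the
    generating-equation truth, recorded in the answer key.
    """
    root_seq = np.random.SeedSequence(seed)
    (tree_seq, trait_seq, meas_seq, fossil_seq) = root_seq.spawn(4)
    tree_rngs = [np.random.default_rng(s) for s in tree_seq.spawn(len(clades))]
    trait_rngs = [np.random.default_rng(s) for s in trait_seq.spawn(len(clades))]
    meas_rngs = [np.random.default_rng(s) for s in meas_seq.spawn(len(clades))]

    subtrees, frames, all_rows, tip_map = [], [], [], {}
    answer_key: dict = {"seed": seed, "clades": {}}
    for params, t_rng, tr_rng, m_rng in zip(clades, tree_rngs, trait_rngs, meas_rngs):
        prefix = _CLADE_PREFIX[params.clade]
        labels = [f"{prefix}{i + 1}" for i in range(params.n_tips)]
        newick, depth = _yule_newick(labels, params.birth_rate, t_rng)
        subtrees.append((newick, depth))
        subtree = parse_newick(newick + ";")
        traits = simulate_clade_traits(subtree, params, tr_rng)
        ratites: set[str] = set()
        if params.n_ratites:
            ratites = set(
                traits.nsmallest(params.n_ratites, params.predictor)["taxon"]
            )
        rows = _rows_from_traits(traits, params, m_rng, ratites)
        all_rows.extend(rows)
        frames.append(traits)
        tip_map.update(dict(zip(traits["taxon"], traits["tree_tip"])))
        answer_key["clades"][params.clade] = {
            "slope": params.slope,
            "intercept": params.intercept,
            "residual_sd": params.residual_sd,
            "predictor": params.predictor,
            "n": params.n_tips,
            "ratites": sorted(ratites),
        }

    # graft clade subtrees onto one root, padding stems so tips stay coeval
    max_depth = max(d for _, d in subtrees)
    parts = [f"{nwk}:{max_depth - d + 1.0:.10g}" for nwk, d in subtrees]
    joint_tree = parse_newick("(" + ",".join(parts) + ");")

    # fossils: same generative law, reference = noiseless truth
    fossil_clades = ("theropod", "sauropodomorph", "ornithischian")
    f_tree_rngs = [np.random.default_rng(s) for s in fossil_seq.spawn(2 * len(fossil_clades))]
    fossil_rows, fossil_parts, reference = [], [], {}
    gen_eq = {"slope": 1.375, "intercept": -0.374, "predictor": "C_index"}
    for ci, clade in enumerate(fossil_clades):
        prefix = _CLADE_PREFIX[clade]
        labels = [f"{prefix}{i + 1}" for i in range(n_fossils_per_clade)]
        newick, depth = _yule_newick(labels, 1.0, f_tree_rngs[2 * ci])
        fossil_parts.append((newick, depth))
        rng = f_tree_rngs[2 * ci + 1]
        log_index = rng.normal(0.0, 0.12, size=n_fossils_per_clade)
        fem = _FEMORAL_CONSTANTS[clade]
        for label, lx in zip(labels, log_index):
            index = 10.0**lx
            relcom = 10.0 ** (gen_eq["slope"] * lx + gen_eq["intercept"])
            size = float(np.exp(rng.normal(0.0, 0.3)))
            f = {k: v * size for k, v in fem.items()}
            fossil_rows.append(
                StylopodMeasurements(
                    taxon=label,
                    clade=clade,
                    FC=f["FC"], FW1=f["FW1"], FW2=f["FW2"], FL=f["FL"],
                    HC=f["FC"] * index,
                    HW1=f["FW1"] * index,
                    HW2=f["FW2"] * index,
                    HL=f["FL"] * (0.8 + 0.2 * index),
                )
            )
            reference[label] = relcom
    f_max = max(d for _, d in fossil_parts)
    fossil_tree = parse_newick(
        "(" + ",".join(f"{nwk}:{f_max - d + 1.0:.10g}" for nwk, d in fossil_parts) + ");"
    )
    answer_key["fossil_generating_equation"] = gen_eq

    return StudyFixture(
        extant_rows=all_rows,
        extant_frame=measurements_frame(all_rows),
        tree=joint_tree,
        tip_map=tip_map,
        fossil_rows=fossil_rows,
        fossil_frame=measurements_frame(fossil_rows),
        fossil_tree=fossil_tree,
        fossil_reference=reference,
        answer_key=answer_key,
    )
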
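"""Built-in toy metabolic models and reference networks.

Every simulation and test in the package can run without downloading
anything: these small, pinned stoichiometries stand in for curated
genome-scale (and reduced) models.  They are invented but carbon-balanced,
and their route structure encodes the mechanisms that matter:

* ``toy_aerobe`` — an obligate aerobe on glucose: no electron acceptor, no
  ATP, no growth.
* ``toy_facultative`` — glucose oxidation through three routes whose ATP
  yields are ordered aerobic (30) > denitrification (12) > overflow
  fermentation (2, excreting acetate), plus aerobic acetate re-assimilation.
  The LP therefore prefers oxygen, falls back to nitrate, and only
  overflows — excreting acetate — when electron acceptors run short.
* ``toy_pair`` — an obligate cross-feeding pair: partner A consumes lactose
  but cannot grow without methionine and excretes acetate when oxygen is
  limiting; partner B grows only on that acetate and exports methionine
  stoichiometrically coupled to its biomass reaction.  Neither grows alone.

Yields are chosen so maximum growth rates sit in a realistic 0.3-0.8 h^-1
band at the default uptake caps (glucose 8 mmol gDW^-1 h^-1 etc.).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .metabolism import MetabolicModel, parse_equation
from . import network as netmod

__all__ = [
    "make_toy_aerobe",
    "make_toy_facultative",
    "make_toy_pair",
    "toy_model",
    "reference_lattices",
    "make_golden",
]


def _build(name, biomass, rows, exchanges, max_uptake, carbon, biomass_carbon):
    reactions = [r[0] for r in rows]
    equations = {r[0]: r[1] for r in rows}
    lb = np.array([r[2] for r in rows], dtype=float)
    ub = np.array([r[3] for r in rows], dtype=float)
    mets: list[str] = []
    seen = set()
    stoichs = {}
    for rid, eq, *_ in rows:
        stoich = parse_equation(rid, eq)
        stoichs[rid] = stoich
        for m in stoich:
            if m not in seen:
                seen.add(m)
                mets.append(m)
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(reactions):
        for m, c in stoichs[rid].items():
            S[midx[m], j] = c
    return MetabolicModel(
        name=name, metabolites=mets, reactions=reactions, S=S, lb=lb, ub=ub,
        biomass=biomass, exchanges=exchanges, max_uptake=max_uptake,
        carbon=carbon, biomass_carbon=biomass_carbon, equations=equations,
    )


def make_toy_aerobe() -> MetabolicModel:
    """Obligate aerobe: glucose + O2 -> biomass; mu = 0 without oxygen."""
    rows = [
        ("EX_glc", "glc_e <->", -1000, 1000),
        ("EX_o2", "o2_e <->", -1000, 1000),
        ("EX_co2", "co2_e ->", 0, 1000),
        ("T_glc", "glc_e -> glc_c", 0, 1000),
        ("T_o2", "o2_e -> o2_c", 0, 1000),
        ("T_co2", "co2_c -> co2_e", 0, 1000),
        ("AER", "glc_c + 6 o2_c -> 6 co2_c + 30 atp", 0, 1000),
        ("BIO", "10 glc_c + 100 atp ->", 0, 1000),
    ]
    return _build(
        "toy_aerobe", "BIO", rows,
        exchanges={"glucose": "EX_glc", "oxygen": "EX_o2"},
        max_uptake={"glucose": 8.0, "oxygen": 30.0},
        carbon={"glc_e": 6, "glc_c": 6, "co2_e": 1, "co2_c": 1},
        biomass_carbon=60.0,
    )


def make_toy_facultative() -> MetabolicModel:
    """Facultative anaerobe with aerobic, denitrifying and overflow routes."""
    rows = [
        ("EX_glc", "glc_e <->", -1000, 1000),
        ("EX_o2", "o2_e <->", -1000, 1000),
        ("EX_no3", "no3_e <->", -1000, 1000),
        ("EX_ac", "ac_e <->", -1000, 1000),
        ("EX_co2", "co2_e ->", 0, 1000),
        ("EX_n2", "n2_e ->", 0, 1000),
        ("T_glc", "glc_e -> glc_c", 0, 1000),
        ("T_o2", "o2_e -> o2_c", 0, 1000),
        ("T_no3", "no3_e -> no3_c", 0, 1000),
        ("T_ac", "ac_e <-> ac_c", -1000, 1000),
        ("T_co2", "co2_c -> co2_e", 0, 1000),
        ("T_n2", "n2_c -> n2_e", 0, 1000),
        ("AER", "glc_c + 6 o2_c -> 6 co2_c + 30 atp", 0, 1000),
        ("DEN", "glc_c + 4.8 no3_c -> 6 co2_c + 2.4 n2_c + 12 atp", 0, 1000),
        ("OVF", "glc_c -> 2 ac_c + 2 co2_c + 2 atp", 0, 1000),
        ("ACR", "ac_c + 2 o2_c -> 2 co2_c + 8 atp", 0, 1000),
        ("GNG", "3 ac_c + 10 atp -> glc_c", 0, 1000),
        ("BIO", "10 glc_c + 100 atp ->", 0, 1000),
    ]
    return _build(
        "toy_facultative", "BIO", rows,
        exchanges={
            "glucose": "EX_glc", "oxygen": "EX_o2",
            "nitrate": "EX_no3", "acetate": "EX_ac",
        },
        max_uptake={"glucose": 8.0, "oxygen": 30.0, "nitrate": 20.0, "acetate": 10.0},
        carbon={
            "glc_e": 6, "glc_c": 6, "ac_e": 2, "ac_c": 2, "co2_e": 1, "co2_c": 1,
        },
        biomass_carbon=60.0,
    )


def make_toy_pair() -> tuple[MetabolicModel, MetabolicModel]:
    """Obligate mutualists: (A) lactose consumer, methionine auxotroph,
    acetate excreter; (B) acetate consumer, methionine producer."""
    rows_a = [
        ("EX_lcts", "lcts_e <->", -1000, 1000),
        ("EX_o2", "o2_e <->", -1000, 1000),
        ("EX_met", "met_e <->", -1000, 1000),
        ("EX_ac", "ac_e ->", 0, 1000),
        ("EX_co2", "co2_e ->", 0, 1000),
        ("T_lcts", "lcts_e -> lcts_c", 0, 1000),
        ("T_o2", "o2_e -> o2_c", 0, 1000),
        ("T_met", "met_e -> met_c", 0, 1000),
        ("T_ac", "ac_c -> ac_e", 0, 1000),
        ("T_co2", "co2_c -> co2_e", 0, 1000),
        ("LAER", "lcts_c + 12 o2_c -> 12 co2_c + 60 atp", 0, 1000),
        ("LOVF", "lcts_c -> 4 ac_c + 4 co2_c + 4 atp", 0, 1000),
        ("BIO_A", "5 lcts_c + 0.5 met_c + 100 atp ->", 0, 1000),
    ]
    a = _build(
        "toy_pair_a", "BIO_A", rows_a,
        exchanges={
            "lactose": "EX_lcts", "oxygen": "EX_o2",
            "methionine": "EX_met", "acetate": "EX_ac",
        },
        # microaerobic oxygen cap keeps part of the lactose flux fermentative,
        # so acetate is excreted whenever A grows fast
        max_uptake={"lactose": 2.0, "oxygen": 5.0, "methionine": 1.0, "acetate": 0.0},
        carbon={
            "lcts_e": 12, "lcts_c": 12, "ac_e": 2, "ac_c": 2,
            "met_e": 2, "met_c": 2, "co2_e": 1, "co2_c": 1,
        },
        biomass_carbon=61.0,
    )
    rows_b = [
        ("EX_ac", "ac_e <->", -1000, 1000),
        ("EX_o2", "o2_e <->", -1000, 1000),
        ("EX_met", "met_e ->", 0, 1000),
        ("EX_co2", "co2_e ->", 0, 1000),
        ("T_ac", "ac_e -> ac_c", 0, 1000),
        ("T_o2", "o2_e -> o2_c", 0, 1000),
        ("T_met", "met_c -> met_e", 0, 1000),
        ("T_co2", "co2_c -> co2_e", 0, 1000),
        ("ACR", "ac_c + 2 o2_c -> 2 co2_c + 8 atp", 0, 1000),
        ("BIO_B", "6 ac_c + 50 atp -> 1.5 met_c", 0, 1000),
    ]
    b = _build(
        "toy_pair_b", "BIO_B", rows_b,
        exchanges={"acetate": "EX_ac", "oxygen": "EX_o2", "methionine": "EX_met"},
        max_uptake={"acetate": 10.0, "oxygen": 30.0, "methionine": 0.0},
        carbon={
            "ac_e": 2, "ac_c": 2, "met_e": 2, "met_c": 2, "co2_e": 1, "co2_c": 1,
        },
        biomass_carbon=9.0,  # 12 C in - 3 C to methionine
    )
    return a, b


_FACTORIES = {
    "toy_aerobe": make_toy_aerobe,
    "toy_facultative": make_toy_facultative,
    "toy_pair_a": lambda: make_toy_pair()[0],
    "toy_pair_b": lambda: make_toy_pair()[1],
}


def toy_model(name: str) -> MetabolicModel:
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown toy model {name!r}; options: {sorted(_FACTORIES)}")


def reference_lattices() -> dict[str, netmod.PoreNetwork]:
    """Small deterministic reference networks used across the test-suite."""
    return {
        "chain-100": netmod.build_chain(100, 2000e-6 / 99),
        "square-3x3": netmod.build_lattice("square", 3, 3, 1e-4),
        "hex-20x20": netmod.build_lattice("hexagonal", 20, 20, 1e-4),
        "disc-2mm": netmod.build_aggregate_domain(2e-3, "hexagonal", 1e-4),
    }


def make_golden(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the full fixture set and return a name -> sha256 manifest.

    Regeneration with the same seed is bit-identical; the manifest file
    itself is written alongside the fixtures.
    """
    from .metabolism import write_tabular
    from .hydrology import classify_saturation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _FACTORIES:
        write_tabular(toy_model(name), out / f"{name}.tsv")
    lattices = reference_lattices()
    for name, net in lattices.items():
        hydrated = netmod.sample_pore_geometries(net, 10e-6, 5e-6, seed=seed,
                                                 quantity="diameter")
        hydrated.write(out / f"{name}.nodes.tsv", out / f"{name}.pores.tsv")
        air = "periphery" if "periphery" in hydrated.boundary_sets else "edge"
        rows = ["psi\tpore\tA_w\tWFT\tsaturated"]
        for psi in (-100.0, -1000.0, -10000.0):
            st = classify_saturation(hydrated, psi, air_boundary=air)
            for j in range(hydrated.n_pores):
                rows.append(
                    f"{psi:g}\t{j}\t{st.water_area[j]:.12e}\t"
                    f"{st.film[j]:.12e}\t{int(st.saturated[j])}"
                )
        (out / f"{name}.hydration.tsv").write_text("\n".join(rows) + "\n")
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "MANIFEST.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def verify_golden(out_dir) -> list[str]:
    """Names whose content hash no longer matches the committed manifest."""
    out = Path(out_dir)
    manifest = json.loads((out / "MANIFEST.json").read_text())
    bad = []
    for name, digest in manifest.items():
        p = out / name
        if not p.exists() or hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            bad.append(name)
    return bad
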
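"""Build the packaged MZRW fixture CSVs under src/focuspharm/data/.

The compound structures are stand-ins: the source tables print compound
names, herb origins and detection flags but not structures, so each named
compound carries a literature-style structure (or a chemotype-consistent
analog for minor congeners) sufficient for the chemical-space analysis to
behave like the real library. See data/FIXTURES.md.

Run from the repository root:  python scripts/build_mzrw_fixtures.py
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

from rdkit import Chem

DATA = Path(__file__).resolve().parent.parent / "src" / "focuspharm" / "data"

GLC = "OC8OC(CO)C(O)C(O)C8O"  # O-linked glucopyranosyl, ring digits kept clear of cores
RUT = "OC8OC(COC9OC(C)C(O)C(O)C9O)C(O)C(O)C8O"   # rutinosyl: rha(1->6)glc
NEO = "OC8OC(CO)C(O)C(O)C8OC9OC(C)C(O)C(O)C9O"   # neohesperidosyl: rha(1->2)glc


def flavanone(aryl: str, sugar: str | None) -> str:
    o7 = f"O{sugar[1:]}" if sugar else "O"
    return f"O=C1CC({aryl})Oc2cc({o7})cc(O)c12" if sugar else f"O=C1CC({aryl})Oc2cc(O)cc(O)c12"


NARINGENIN_AR = "c2ccc(O)cc2"
HESPERETIN_AR = "c2ccc(OC)c(O)c2"
ISOSAKURANETIN_AR = "c2ccc(OC)cc2"
ERIODICTYOL_AR = "c2ccc(O)c(O)c2"


def paeoniflorin_like(acyl_aryl: str) -> str:
    """Monoterpene-glycoside stand-in: pinane-type core + glucose + aroyl ester."""
    return f"CC1(C)C2CC(O{GLC[1:]})C1(COC(=O){acyl_aryl})CC2(C)O"


ANTHRA = "O=C1c2cc({0})cc(O)c2C(=O)c2cc({1})c({2})cc12"

# name -> (smiles, herb)
COMPOUNDS: dict[str, tuple[str, str]] = {}


def add(name: str, smiles: str, herb: str) -> None:
    if name in COMPOUNDS:
        raise ValueError(f"duplicate name {name}")
    COMPOUNDS[name] = (smiles, herb)


# --- HMR: fatty acids -------------------------------------------------------
add("linoleic_acid", r"CCCCC/C=C\C/C=C\CCCCCCCC(=O)O", "HMR")
add("oleic_acid", r"CCCCCCCC/C=C\CCCCCCCC(=O)O", "HMR")
add("alpha_linolenic_acid", r"CC/C=C\C/C=C\C/C=C\CCCCCCCC(=O)O", "HMR")
add("palmitic_acid", "CCCCCCCCCCCCCCCC(=O)O", "HMR")
add("stearic_acid", "CCCCCCCCCCCCCCCCCC(=O)O", "HMR")
add("sativic_acid", "CCCCCC(O)C(O)C(O)C(O)CCCCCCCC(=O)O", "HMR")
add("arachidic_acid", "CCCCCCCCCCCCCCCCCCCC(=O)O", "HMR")

# --- DH: anthraquinones, stilbenes, gallates, catechins ---------------------
add("emodin", "Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O", "DH")
add("chrysophanol", "Cc1cc2C(=O)c3cccc(O)c3C(=O)c2c(O)c1", "DH")
add("physcion", "COc1cc(O)c2c(c1)C(=O)c1cc(C)cc(O)c1C2=O", "DH")
add("aloe_emodin", "OCc1cc2C(=O)c3cccc(O)c3C(=O)c2c(O)c1", "DH")
add("rhein", "O=C(O)c1cc2C(=O)c3cccc(O)c3C(=O)c2c(O)c1", "DH")
add("citreorosein", "OCc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O", "DH")
add("questin", "Cc1cc(OC)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O", "DH")

add("emodin_8_O_glucoside", f"Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc({GLC})c1C2=O", "DH")
add("emodin_1_O_glucoside", f"Cc1cc({GLC})c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O", "DH")
add("chrysophanol_8_O_glucoside", f"Cc1cc2C(=O)c3cccc({GLC})c3C(=O)c2c(O)c1", "DH")
add("chrysophanol_1_O_glucoside", f"Cc1cc2C(=O)c3cccc(O)c3C(=O)c2c({GLC})c1", "DH")
add("physcion_8_O_glucoside", f"COc1cc({GLC})c2c(c1)C(=O)c1cc(C)cc(O)c1C2=O", "DH")
add("aloe_emodin_8_O_glucoside", f"OCc1cc2C(=O)c3cccc({GLC})c3C(=O)c2c(O)c1", "DH")
add("rhein_8_O_glucoside", f"O=C(O)c1cc2C(=O)c3cccc({GLC})c3C(=O)c2c(O)c1", "DH")

add("resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1", "DH")
add("polydatin", f"Oc1ccc(/C=C/c2cc(O)cc({GLC})c2)cc1", "DH")
add("rhapontigenin", "COc1ccc(/C=C/c2cc(O)cc(O)c2)cc1O", "DH")
add("rhaponticin", f"COc1ccc(/C=C/c2cc(O)cc({GLC})c2)cc1O", "DH")
add("piceatannol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1O", "DH")
add("piceatannol_glucoside", f"Oc1ccc(/C=C/c2cc(O)cc({GLC})c2)cc1O", "DH")
add("isorhapontigenin", "COc1cc(/C=C/c2cc(O)cc(O)c2)ccc1O", "DH")
add("isorhapontin", f"COc1cc(/C=C/c2cc(O)cc({GLC})c2)ccc1O", "DH")

add("gallic_acid", "O=C(O)c1cc(O)c(O)c(O)c1", "DH")
add("protocatechuic_acid", "O=C(O)c1ccc(O)c(O)c1", "DH")
add("vanillic_acid", "COc1cc(C(=O)O)ccc1O", "DH")
add("syringic_acid", "COc1cc(C(=O)O)cc(OC)c1O", "DH")
add("methyl_gallate", "COC(=O)c1cc(O)c(O)c(O)c1", "DH")
add("ethyl_gallate", "CCOC(=O)c1cc(O)c(O)c(O)c1", "DH")

add("catechin", "Oc1cc(O)c2c(c1)O[C@H](c1ccc(O)c(O)c1)[C@H](O)C2", "DH")
add("epicatechin", "Oc1cc(O)c2c(c1)O[C@H](c1ccc(O)c(O)c1)[C@@H](O)C2", "DH")
add("epicatechin_gallate",
    "Oc1cc(O)c2c(c1)O[C@H](c1ccc(O)c(O)c1)[C@@H](OC(=O)c1cc(O)c(O)c(O)c1)C2", "DH")
add("gallocatechin", "Oc1cc(O)c2c(c1)O[C@H](c1cc(O)c(O)c(O)c1)[C@H](O)C2", "DH")

# minor anthraquinone congeners (chemotype-consistent analogs)
_VARIANTS = [
    ("rheum_anthraquinone_A", ("CC", "O", "O")),
    ("rheum_anthraquinone_B", ("C", "OC", "O")),
    ("rheum_anthraquinone_C", ("CO", "O", "OC")),
    ("rheum_anthraquinone_D", ("C", "Cl", "O")),
    ("rheum_anthraquinone_E", ("O", "O", "O")),
    ("rheum_anthraquinone_F", ("C", "O", "N")),
    ("rheum_anthraquinone_G", ("CC", "OC", "O")),
    ("rheum_anthraquinone_H", ("C", "C", "O")),
    ("rheum_anthraquinone_I", ("CO", "C", "O")),
]
for name, subs in _VARIANTS:
    add(name, ANTHRA.format(*subs), "DH")
add("rheum_anthraquinone_J", ANTHRA.format("OC", "O", "O"), "DH")
add("gallic_acid_glucoside",
    "O=C(O)c1cc(O)c(OC8OC(CO)C(O)C(O)C8O)c(O)c1", "DH")
_GLC_VARIANTS = [
    ("rheum_anthraquinone_glucoside_E", ("O", GLC, "O")),
    ("rheum_anthraquinone_glucoside_A", ("C", GLC, "O")),
    ("rheum_anthraquinone_glucoside_B", ("CC", GLC, "O")),
    ("rheum_anthraquinone_glucoside_C", ("C", GLC, "OC")),
    ("rheum_anthraquinone_glucoside_D", ("CO", GLC, "O")),
]
for name, subs in _GLC_VARIANTS:
    add(name, ANTHRA.format(*subs), "DH")

# --- KXR: cyanogenic glycosides ---------------------------------------------
add("amygdalin",
    "N#CC(OC8OC(COC9OC(CO)C(O)C(O)C9O)C(O)C(O)C8O)c1ccccc1", "KXR")
add("prunasin", "N#C[C@@H](OC8OC(CO)C(O)C(O)C8O)c1ccccc1", "KXR")
add("sambunigrin", "N#C[C@H](OC8OC(CO)C(O)C(O)C8O)c1ccccc1", "KXR")

# --- BS: monoterpene glycosides + phenolics ---------------------------------
add("paeoniflorin", paeoniflorin_like("c1ccccc1"), "BS")
add("albiflorin", f"CC1(C)C2CC(OC(=O)c3ccccc3)C1(CO{GLC[1:]})CC2(C)O", "BS")
add("oxypaeoniflorin", paeoniflorin_like("c1ccc(O)cc1"), "BS")
add("galloylpaeoniflorin", paeoniflorin_like("c1cc(O)c(O)c(O)c1"), "BS")
add("benzoylpaeoniflorin", paeoniflorin_like("c1ccc(C)cc1"), "BS")
add("mudanpioside_like", paeoniflorin_like("c1ccc(O)c(OC)c1"), "BS")
add("desbenzoylpaeoniflorin_like", f"CC1(C)C2CC(O{GLC[1:]})C1(COC(C)=O)CC2(C)O", "BS")
add("paeoniflorigenone_like", "CC1(C)C2CC(O)C1(COC(=O)c1ccccc1)CC2(C)O", "BS")
add("lactiflorin_like", paeoniflorin_like("c1ccc(OCC)cc1"), "BS")
add("paeonidanin_like", paeoniflorin_like("c1ccc(CC)cc1"), "BS")
add("paeonol", "CC(=O)c1ccc(O)cc1OC", "BS")
add("oxypaeonol", "CC(=O)c1ccc(O)c(O)c1", "BS")
add("benzoic_acid", "O=C(O)c1ccccc1", "BS")
add("digalloyl_glucose",
    "OCC8OC(OC(=O)c1cc(O)c(O)c(O)c1)C(O)C(O)C8OC(=O)c1cc(O)c(O)c(O)c1", "BS")

# --- HP: biphenyl neolignans + others ---------------------------------------
add("honokiol", "C=CCc1ccc(O)c(-c2ccc(CC=C)cc2O)c1", "HP")
add("magnolol", "C=CCc1ccc(O)c(-c2cc(CC=C)ccc2O)c1", "HP")
add("methylhonokiol", "C=CCc1ccc(OC)c(-c2ccc(CC=C)cc2O)c1", "HP")
add("methylmagnolol", "C=CCc1ccc(OC)c(-c2cc(CC=C)ccc2O)c1", "HP")
add("dihydrohonokiol", "CCCc1ccc(O)c(-c2ccc(CC=C)cc2O)c1", "HP")
add("obovatol_like", "C=CCc1ccc(O)c(-c2cc(CC=C)cc(O)c2O)c1", "HP")
add("syringin", f"COc1cc(/C=C/CO)cc(OC)c1{GLC}", "HP")
add("magnoloside_like", f"OCC8OC(OCCc1ccc(O)c(O)c1)C(O)C(O)C8O", "HP")
add("eudesmol_like", "CC(C)(O)C1CCC2(C)CCCC(=C)C2C1", "HP")
add("piperonal_like", "O=Cc1ccc2OCOc2c1", "HP")

# --- ZS: flavanones and their glycosides ------------------------------------
add("naringin", flavanone(NARINGENIN_AR, NEO), "ZS")
add("narirutin", flavanone(NARINGENIN_AR, RUT), "ZS")
add("hesperidin", flavanone(HESPERETIN_AR, RUT), "ZS")
add("neohesperidin", flavanone(HESPERETIN_AR, NEO), "ZS")
add("poncirin", flavanone(ISOSAKURANETIN_AR, NEO), "ZS")
add("didymin", flavanone(ISOSAKURANETIN_AR, RUT), "ZS")
add("eriocitrin", flavanone(ERIODICTYOL_AR, RUT), "ZS")
add("naringenin", flavanone(NARINGENIN_AR, None), "ZS")
add("hesperetin", flavanone(HESPERETIN_AR, None), "ZS")
add("isosakuranetin", flavanone(ISOSAKURANETIN_AR, None), "ZS")
add("eriodictyol", flavanone(ERIODICTYOL_AR, None), "ZS")
add("nobiletin", "COc1ccc(-c2cc(=O)c3c(OC)c(OC)c(OC)c(OC)c3o2)cc1OC", "ZS")
add("tangeretin", "COc1ccc(-c2cc(=O)c3c(OC)c(OC)c(OC)c(OC)c3o2)cc1", "ZS")
add("sinensetin", "COc1cc(-c2cc(=O)c3c(OC)c(OC)c(OC)cc3o2)ccc1OC", "ZS")
add("synephrine", "CNCC(O)c1ccc(O)cc1", "ZS")

# --- detection flags, ranks, annotations ------------------------------------
PLASMA_AND_FECES = {
    "emodin", "aloe_emodin", "rhein", "honokiol", "magnolol",
    "naringin", "neohesperidin", "amygdalin", "paeoniflorin",
}
PLASMA_ONLY = {
    "chrysophanol", "physcion", "gallic_acid", "catechin", "epicatechin",
    "resveratrol", "polydatin", "rhaponticin", "prunasin", "albiflorin",
    "oxypaeoniflorin", "hesperidin", "narirutin", "poncirin", "hesperetin",
    "sambunigrin", "galloylpaeoniflorin", "benzoylpaeoniflorin", "paeonol",
    "syringin", "protocatechuic_acid", "vanillic_acid", "methyl_gallate",
    "ethyl_gallate", "emodin_8_O_glucoside",
}
FECES_ONLY = {"naringenin"}  # metabolite, absent from the extract

RANKS = {
    "emodin": 1, "rhein": 2, "chrysophanol": 3, "aloe_emodin": 4, "physcion": 5,
    "amygdalin": 1, "prunasin": 2, "sambunigrin": 3,
    "albiflorin": 1, "paeoniflorin": 2, "oxypaeoniflorin": 3,
    "honokiol": 1, "magnolol": 2,
    "naringin": 1, "neohesperidin": 2, "hesperidin": 3,
}

# the reference standards: commercially available, common in pharmacology work
STANDARDS = {
    "gallic_acid", "amygdalin", "paeoniflorin", "hesperidin", "neohesperidin",
    "naringin", "magnolol", "honokiol", "aloe_emodin", "physcion",
    "chrysophanol", "emodin", "albiflorin", "rhein",
}

GROUP_MEMBERS = {
    "SM2": ["emodin", "chrysophanol", "physcion", "aloe_emodin", "rhein",
            "citreorosein", "questin"],
    "SM3": ["amygdalin", "prunasin", "sambunigrin"],
    "SM4": ["albiflorin", "paeoniflorin", "oxypaeoniflorin",
            "galloylpaeoniflorin", "benzoylpaeoniflorin", "mudanpioside_like"],
    "SM5": ["honokiol", "magnolol", "methylhonokiol", "methylmagnolol",
            "dihydrohonokiol", "obovatol_like"],
    "SM6": ["naringin", "narirutin", "hesperidin", "neohesperidin",
            "poncirin", "didymin", "eriocitrin"],
}

REPRESENTATIVES = ["emodin", "amygdalin", "albiflorin", "honokiol", "naringin"]

TABLE1_REFERENCED = {
    "emodin": ["ESR1", "ESR2", "CSNK2A1", "EPHX2", "PTP4A3", "LCK", "ELANE"],
    "honokiol": ["PTGS1", "PTGS2", "ALOX5", "CNR1", "CNR2", "GABA_A", "RXR"],
    "naringin": ["CYP19A1"],
}
TABLE1_PREDICTED = {
    "emodin": ["ESR2", "ESR1", "SRC", "PIM1", "IGF1R", "PPARG", "CYP1B1", "MET",
               "AKR1B1", "ALOX5", "FLT3", "CSNK2A1", "AXL", "TNKS2"],
    "amygdalin": ["SLC5A4", "ACHE", "SLC5A1", "P2RY14", "SLC5A2", "CA14", "CA12",
                  "CA2", "CA9", "CA1"],
    "albiflorin": ["SLC5A4", "SLC5A1", "SLC5A2", "CA12", "CA2", "CA14", "CA9"],
    "honokiol": ["CYP19A1", "ESR2", "HSD17B2", "HSD17B1", "ESR1", "SLC22A6", "MIF"],
    "naringin": ["ACHE", "SLC5A4", "AKR1B1", "SLC5A2", "ADORA1", "CA14", "CA12",
                 "SLC5A1", "CA2", "CA9", "CA1"],
}
TABLE2_EVIDENCE = [
    # target, pathway, linked compounds (note), citation tag
    ("ACHE", "acetylcholine", "amygdalin;naringin", "cit:ACHE-GI"),
    ("ADORA1", "purine", "naringin", "cit:adenosine-constipation"),
    ("CNR1", "cannabinoid", "honokiol", "cit:CNR1-motility"),
    ("CYP19A1", "estrogen", "honokiol;naringin", "cit:aromatase-estrogen"),
    ("ESR2", "estrogen", "emodin;honokiol", "cit:ESR2-defecation"),
    ("PTGS1", "prostaglandin", "honokiol", "cit:PTGS1-STC"),
    ("PTGS2", "prostaglandin", "honokiol", "cit:PTGS2-STC"),
]


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    herbs_order = {"HMR": 0, "DH": 1, "KXR": 2, "BS": 3, "HP": 4, "ZS": 5}

    seen_canonical: dict[str, str] = {}
    rows = []
    for name, (smi, herb) in COMPOUNDS.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SystemExit(f"INVALID SMILES for {name}: {smi}")
        can = Chem.MolToSmiles(mol)
        if can in seen_canonical:
            raise SystemExit(f"DUPLICATE structure: {name} == {seen_canonical[can]}")
        seen_canonical[can] = name
        in_feces = name in PLASMA_AND_FECES or name in FECES_ONLY
        in_plasma = name in PLASMA_AND_FECES or name in PLASMA_ONLY
        in_extract = name not in FECES_ONLY
        rows.append({
            "compound_id": name,
            "name": name.replace("_", " "),
            "smiles": can,
            "herb": herb,
            "in_extract": int(in_extract),
            "in_plasma": int(in_plasma),
            "in_feces": int(in_feces),
            "abundance_rank": RANKS.get(name, ""),
            "available": 1 if name in STANDARDS else "",
            "pharmacology_use": 1 if name in STANDARDS else "",
        })
    rows.sort(key=lambda r: (herbs_order[r["herb"]], r["compound_id"]))

    counts: dict[str, int] = {}
    for r in rows:
        counts[r["herb"]] = counts.get(r["herb"], 0) + 1
    print("herb counts:", counts, "total:", len(rows))
    assert counts == {"HMR": 7, "DH": 48, "KXR": 3, "BS": 14, "HP": 10, "ZS": 15}

    def write_csv(fname: str, fieldnames: list[str], data: list[dict]) -> None:
        with open(DATA / fname, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=fieldnames)
            w.writeheader()
            w.writerows(data)

    write_csv("mzrw_compounds.csv",
              ["compound_id", "name", "smiles", "herb", "in_extract", "in_plasma",
               "in_feces", "abundance_rank", "available", "pharmacology_use"], rows)

    write_csv("mzrw_table1_referenced.csv", ["compound_id", "target_id", "citation_tag"],
              [{"compound_id": c, "target_id": t, "citation_tag": f"cit:{c}-{t}"}
               for c, ts in TABLE1_REFERENCED.items() for t in ts])
    write_csv("mzrw_table1_predicted.csv", ["compound_id", "target_id", "detail"],
              [{"compound_id": c, "target_id": t, "detail": "most-similar-ligand"}
               for c, ts in TABLE1_PREDICTED.items() for t in ts])
    write_csv("mzrw_table2_evidence.csv",
              ["target_id", "disorder", "pathway", "note", "citation_tag"],
              [{"target_id": t, "disorder": "constipation", "pathway": p,
                "note": f"linked:{linked}", "citation_tag": cit}
               for t, p, linked, cit in TABLE2_EVIDENCE])
    by_id = {r["compound_id"]: r for r in rows}
    write_csv("mzrw_representatives.csv", ["compound_id", "smiles"],
              [{"compound_id": c, "smiles": by_id[c]["smiles"]} for c in REPRESENTATIVES])
    write_csv("mzrw_group_members.csv", ["group_label", "compound_id"],
              [{"group_label": g, "compound_id": c}
               for g, cs in GROUP_MEMBERS.items() for c in cs])

    manifest = {}
    for f in sorted(DATA.glob("mzrw_*.csv")):
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (DATA / "checksums.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print("wrote", len(manifest), "fixture files + checksums.json")


if __name__ == "__main__":
    main()
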
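"""Shared fixtures: the published rule table, random databases, and
brute-force oracles kept independent of the library code paths."""

from __future__ import annotations

import numpy as np
import pytest

from herbnet import Prescription, TransactionDB

# Published disease ⇒ material association table: per rule
# (support %, confidence %, lift) over N = 505 prescriptions.
# Shared materials carry mutually inconsistent marginals across diseases
# (each row was reported independently), so rows are reconstructed into
# *separate* databases, never jointly.
TABLE1_N = 505
TABLE1: dict[str, list[tuple[str, float, float, float]]] = {
    "Wound": [
        ("Rumex abyssinicus Jacq.", 1.39, 17.95, 5.33),
        ("Conyza steudelii Sch.-Bip. ex A. Rich.", 1.19, 15.38, 5.55),
        ("Plumbago zeylanica L.", 0.99, 12.82, 2.02),
        ("Calpurnia aurea (Ait.) Benth.", 0.79, 10.26, 2.35),
    ],
    "Mental illness": [
        ("Clerodendrum myricoides (Hochst.) R. Br. ex Vatke", 1.58, 29.63, 3.48),
        ("Ruta chalepensis L.", 1.19, 22.22, 3.87),
        ("Clausena anisata (Willd.) Benth.", 0.79, 14.81, 4.68),
        ("Trigonella foenum-graecum L.", 0.59, 11.11, 7.01),
        ("Cannabis sativa L.", 0.59, 11.11, 5.10),
        ("Withania somnifera (L.) Dunal", 0.59, 11.11, 2.81),
        ("Gladiolus psittacinus Hook.", 0.59, 11.11, 3.74),
        ("Verbena officinalis L.", 0.59, 11.11, 2.95),
        ("Lepidium sativum L.", 0.59, 11.11, 2.95),
        ("Asparagus africanus Lam.", 0.59, 11.11, 2.44),
        ("Securidaca longepedunculata Fresen.", 0.59, 11.11, 2.44),
        ("Capparis tomentosa Lam.", 0.59, 11.11, 2.67),
        ("Adhatoda schimperiana (Hochst) Nees.", 0.59, 11.11, 2.34),
        ("Myrrh (Commiphora cf. crenulata or other C. spp.)", 0.59, 11.11, 2.08),
        ("Cucumis ficifolius A. Rich.", 0.59, 11.11, 1.22),
    ],
    "Sexual stimulation (aphrodisiacs)": [
        ("Tragia pungens (Forssk.) Muell. Arg.", 1.19, 33.33, 28.06),
        ("Asparagus africanus Lam.", 0.99, 27.78, 23.38),
        ("Ferula communis L.", 0.99, 27.78, 9.35),
        ("Thalictrum rhynchocarpum Dill. & A. Rich.", 0.79, 22.22, 4.32),
        ("Phoenix reclinata Jacq.", 0.59, 16.67, 7.65),
        ("Sida cuneifolia Roxb.", 0.59, 16.67, 7.01),
        ("Olea europaea L. subsp. africana (Mill.) P.S. Green", 0.59, 16.67, 6.47),
        ("Gladiolus psittacinus Hook.", 0.59, 16.67, 5.61),
        ("Cucumis ficifolius A. Rich.", 0.59, 16.67, 1.83),
        ("Habenaria sp.", 0.40, 11.11, 28.06),
        ("Sida cuneifolia Roxb. or S. ovata Forssk.", 0.40, 11.11, 9.35),
        ("Tragia pungens (Forssk) Muell. Arg.", 0.40, 11.11, 8.02),
        ("Catha edulis (Vahl) Forssk. ex Endl.", 0.40, 11.11, 9.35),
        ("Stylochiton kerensis N.E. Brown", 0.40, 11.11, 6.23),
        ("Cannabis sativa L.", 0.40, 11.11, 5.10),
        ("Zehneria scabra (L.f.) Sonder", 0.40, 11.11, 2.67),
        ("Clerodendrum myricoides (Hochst.) R. Br. ex Vatke", 0.40, 11.11, 1.30),
    ],
    "Eye disease": [
        ("Hagenia abyssinica (Bruce) J.F. Gmel.", 0.59, 18.75, 7.28),
        ("Premna schimperi Engl.", 0.40, 12.50, 9.02),
        ("Artemisia afra Jacq. ex Willd.", 0.40, 12.50, 7.89),
        ("Vitis vinifera L.", 0.40, 12.50, 5.74),
        ("Solanum marginatum L.f.", 0.40, 12.50, 5.26),
    ],
    "Rabies": [
        ("Cucumis ficifolius A. Rich.", 1.39, 43.75, 4.80),
        ("Phytolacca dodecandra L'Herit.", 0.99, 31.25, 10.52),
        ("Cyphostemma junceum (Webb) Descoings ex Wild & Drummond", 0.79, 25.00, 10.52),
        ("Solanum cf. adoense Hochst.", 0.79, 25.00, 4.86),
        ("Adhatoda schimperiana (Hochst) Nees.", 0.59, 18.75, 3.95),
        ("Sida cuneifolia Roxb. or S. ovata Forssk.", 0.40, 12.50, 10.52),
        ("Senecio myriocephalus Sch. Bip. ex A.Rich.", 0.40, 12.50, 7.01),
        ("Vitis vinifera L.", 0.40, 12.50, 5.74),
        ("Kalanchoe petitiana A. Rich.", 0.40, 12.50, 5.74),
        ("Mandragora officinarum/Luffa aegyptica", 0.40, 12.50, 4.86),
    ],
    "Frequent miscarriage": [
        ("Osyris quadripartita Decne.", 0.59, 18.75, 5.57),
        ("Clutia abyssinica Jaub. & Spach.", 0.59, 18.75, 6.31),
        ("Solanum cf. adoense Hochst.", 0.59, 18.75, 3.64),
        ("Cucumis ficifolius A. Rich.", 0.59, 18.75, 2.06),
        ("Periploca linearifolia A. Rich. & Quart.-Dill.", 0.40, 12.50, 10.52),
        ("Aloe sp.", 0.40, 12.50, 6.31),
        ("Rumex nervosus Vahl", 0.40, 12.50, 4.86),
    ],
    "Leprosy": [
        ("Plumbago zeylanica L.", 0.99, 33.33, 5.26),
        ("Withania somnifera (L.) Dunal", 0.59, 20.00, 5.05),
        ("Euclea schimperi (DC.) Dandy", 0.59, 20.00, 5.61),
        ("Capparis tomentosa Lam.", 0.59, 20.00, 4.81),
        ("Sylvicapra grimmia", 0.40, 13.33, 16.83),
        ("Maesa lanceolata Forssk.", 0.40, 13.33, 22.44),
        ("Ranunculus multifidus Forssk.", 0.40, 13.33, 22.44),
        ("Olea europaea L. subsp. africana (Mill.) P.S. Green", 0.40, 13.33, 5.18),
        ("Osyris quadripartita Decne.", 0.40, 13.33, 3.96),
        ("Clematis simensis Fresen.", 0.40, 13.33, 5.18),
        ("Brucea antidysenterica J.F. Mill.", 0.40, 13.33, 3.96),
        ("Rumex abyssinicus (Jacq.).", 0.40, 13.33, 3.54),
        ("Jasminum floribundum R. Br. ex Fresen.", 0.40, 13.33, 3.06),
        ("Acokanthera schimperi (DC.) Oliv.", 0.40, 13.33, 3.21),
        ("Cucumis ficifolius A. Rich.", 0.40, 13.33, 1.46),
    ],
    "Eczema": [
        ("Hagenia abyssinica (Bruce) J.F. Gmel.", 0.59, 21.43, 8.32),
        ("Cucumis ficifolius A. Rich.", 0.59, 21.43, 2.35),
        ("Lichen", 0.40, 14.29, 14.43),
        ("Gossypium barbadense L.", 0.40, 14.29, 12.02),
        ("Mandragora officinarum/Luffa aegyptica", 0.40, 14.29, 5.55),
        ("Zehneria scabra (L.f.) Sonder", 0.40, 14.29, 3.44),
    ],
    "Menorrhagia": [
        ("Brassica nigra L.", 0.59, 21.43, 12.02),
        ("Protea gaguedi Gmel.", 0.40, 14.29, 36.07),
        ("Cordia africana Lam.", 0.40, 14.29, 10.31),
        ("Nigella sativa L.", 0.40, 14.29, 6.56),
        ("Achyranthes aspera L.", 0.40, 14.29, 3.61),
        ("Asparagus africanus Lam.", 0.40, 14.29, 3.14),
    ],
    "Malaria": [
        ("Dodonaea viscosa (L.) Jack.", 0.59, 25.00, 15.78),
        ("Ekebergia capensis Sparm.", 0.40, 16.67, 12.02),
        ("Kanahia laniflora (Forssk.) R. Br.", 0.40, 16.67, 7.65),
        ("Jasminum floribundum R. Br. ex Fresen.", 0.40, 16.67, 3.83),
        ("Solanum cf. adoens Hochst.", 0.40, 16.67, 3.24),
        ("Clerodendrum myricoides (Hochst.) R. Br. ex Vatke", 0.40, 16.67, 1.96),
    ],
}


def table1_rows() -> list[tuple[str, str, float, float, float]]:
    return [
        (disease, material, s, c, l)
        for disease, rows in TABLE1.items()
        for material, s, c, l in rows
    ]


def random_db(
    rng: np.random.Generator,
    n_transactions: int,
    n_diseases: int,
    n_materials: int,
    p_item: float = 0.3,
) -> TransactionDB:
    """Random transaction database; every row has ≥1 disease, ≥1 material."""
    diseases = [f"d{i}" for i in range(n_diseases)]
    materials = [f"m{i}" for i in range(n_materials)]
    prescriptions = []
    for t in range(n_transactions):
        ds = {d for d in diseases if rng.random() < p_item}
        ms = {m for m in materials if rng.random() < p_item}
        if not ds:
            ds = {diseases[int(rng.integers(n_diseases))]}
        if not ms:
            ms = {materials[int(rng.integers(n_materials))]}
        prescriptions.append(Prescription(f"t{t}", frozenset(ds), frozenset(ms)))
    return TransactionDB(prescriptions)


def brute_force_itemsets(db: TransactionDB, min_support: float) -> dict[frozenset, int]:
    """Exhaustive enumeration of all frequent 1- and 2-itemsets."""
    n = len(db)
    items = db.disease_catalog + db.material_catalog
    baskets = [p.items for p in db.prescriptions]
    out: dict[frozenset, int] = {}
    for i, a in enumerate(items):
        c = sum(1 for b in baskets if a in b)
        if c >= min_support * n:
            out[frozenset([a])] = c
        for b_item in items[i + 1:]:
            c2 = sum(1 for b in baskets if a in b and b_item in b)
            if c2 >= min_support * n:
                out[frozenset([a, b_item])] = c2
    return out


def brute_force_rules(
    db: TransactionDB, min_support: float, min_confidence: float
) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Exhaustive disease⇒material rule counts passing both thresholds."""
    n = len(db)
    baskets = [p.items for p in db.prescriptions]
    out: dict[tuple[str, str], tuple[int, int, int]] = {}
    for d in db.disease_catalog:
        n_d = sum(1 for b in baskets if d in b)
        for m in db.material_catalog:
            n_m = sum(1 for b in baskets if m in b)
            n_both = sum(1 for b in baskets if d in b and m in b)
            if n_d == 0 or n_m == 0 or n_both == 0:
                continue
            if n_both / n >= min_support and n_both / n_d >= min_confidence:
                out[(d, m)] = (n_both, n_d, n_m)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture
def small_db() -> TransactionDB:
    return TransactionDB(
        [
            Prescription("p1", frozenset({"wound"}), frozenset({"A", "B"})),
            Prescription("p2", frozenset({"wound"}), frozenset({"A"})),
            Prescription("p3", frozenset({"fever"}), frozenset({"B", "C"})),
        ]
    )
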
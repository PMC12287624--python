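import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture()
def toy_survey():
    """Two sites; species A in two layers of three plots, B and C smaller."""
    rows = []
    for plot in (1, 2, 3):
        rows += [("S1", plot, "A", "L1"), ("S1", plot, "A", "L2")]
    rows += [("S1", 1, "B", "L1"), ("S1", 2, "B", "L1")]
    rows += [("S1", 1, "C", "L1"), ("S1", 2, "C", "L2"),
             ("S1", 3, "C", "L3"), ("S1", 4, "C", "L4")]
    rows += [("S2", 1, "A", "L1"), ("S2", 1, "B", "L1"), ("S2", 2, "B", "L2")]
    return pd.DataFrame(rows, columns=["site", "plot", "species", "layer"])


@pytest.fixture()
def toy_chemistry():
    """Chemistry for A and B only (C stays unsampled) at both sites."""
    rows = []
    for site, a_n, b_n in (("S1", 2.0, 1.0), ("S2", 1.8, 1.2)):
        rows += [(site, "A", "N", a_n), (site, "B", "N", b_n),
                 (site, "A", "P", a_n / 10), (site, "B", "P", b_n / 10)]
    return pd.DataFrame(rows, columns=["site", "species", "element", "content"])


@pytest.fixture()
def toy_environment():
    return pd.DataFrame({"site": ["S1", "S2"], "rainfall": [700.0, 900.0]})


def loop_cwm(survey: pd.DataFrame, chemistry: pd.DataFrame, element: str):
    """Brute-force per-site CWM oracle: explicit dict loops, no vectorisation.

    Returns {site: (specific, fixed, coverage)} over species that have the
    element at the site, weighting by plot x layer cell counts.
    """
    counts: dict[tuple[str, str], int] = {}
    for _, row in survey.drop_duplicates(["site", "plot", "species", "layer"]).iterrows():
        key = (row["site"], row["species"])
        counts[key] = counts.get(key, 0) + 1
    content: dict[tuple[str, str], float] = {}
    for _, row in chemistry.iterrows():
        if row["element"] == element:
            content[(row["site"], row["species"])] = float(row["content"])
    fixed: dict[str, float] = {}
    for sp in {s for (_, s) in content}:
        vals = [v for (site, s), v in content.items() if s == sp]
        fixed[sp] = sum(vals) / len(vals)
    sites = sorted({s for (s, _) in counts})
    out = {}
    for site in sites:
        present = [(sp, c) for (s, sp), c in counts.items() if s == site]
        sampled = [(sp, c) for sp, c in present if (site, sp) in content]
        if not sampled:
            continue
        total_sampled = sum(c for _, c in sampled)
        total_all = sum(c for _, c in present)
        specific = sum(c / total_sampled * content[(site, sp)] for sp, c in sampled)
        fixed_cwm = sum(c / total_sampled * fixed[sp] for sp, c in sampled)
        out[site] = (specific, fixed_cwm, total_sampled / total_all)
    return out


def loop_decompose(specific, fixed):
    """Cross-product SS oracle with explicit per-site loops."""
    s = list(map(float, specific))
    f = list(map(float, fixed))
    i = [a - b for a, b in zip(s, f)]
    def mean(v):
        return sum(v) / len(v)
    sb, fb, ib = mean(s), mean(f), mean(i)
    ss_total = sum((v - sb) ** 2 for v in s)
    turnover = sum((v - fb) ** 2 for v in f)
    intra = sum((v - ib) ** 2 for v in i)
    cross = 2 * sum((a - fb) * (b - ib) for a, b in zip(f, i))
    return ss_total, turnover, intra, cross


def random_community(rng: np.random.Generator, n_sites=None, n_species=None):
    """Small random survey + chemistry + environment for oracle comparisons."""
    n_sites = n_sites or int(rng.integers(3, 6))
    n_species = n_species or int(rng.integers(2, 5))
    sites = [f"S{i+1}" for i in range(n_sites)]
    species = [chr(ord("A") + k) for k in range(n_species)]
    survey_rows, chem_rows = [], []
    for site in sites:
        present = [sp for sp in species if rng.random() < 0.8] or [species[0]]
        for sp in present:
            cells = rng.choice(21 * 4, size=int(rng.integers(1, 9)), replace=False)
            for cell in cells:
                survey_rows.append((site, int(cell // 4) + 1, sp,
                                    f"L{int(cell % 4) + 1}"))
            if rng.random() < 0.9:
                chem_rows.append((site, sp, "N", float(rng.uniform(0.5, 4.0))))
    # every site needs at least one sampled species
    sampled_sites = {r[0] for r in chem_rows}
    for site in sites:
        if site not in sampled_sites:
            sp = next(r[2] for r in survey_rows if r[0] == site)
            chem_rows.append((site, sp, "N", float(rng.uniform(0.5, 4.0))))
    survey = pd.DataFrame(survey_rows, columns=["site", "plot", "species", "layer"])
    chemistry = pd.DataFrame(chem_rows, columns=["site", "species", "element", "content"])
    environment = pd.DataFrame({"site": sites,
                                "rainfall": rng.uniform(600, 1000, n_sites)})
    return survey, chemistry, environment
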
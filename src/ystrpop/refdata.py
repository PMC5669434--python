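"""Published summary tables from a 17-locus Yfiler survey of five Northern
Iraqi populations (Arab n=102, Kurdish n=104, Syriac n=86, Turkmen n=102,
Yazidi n=106; 500 males in total), plus helpers that rebuild datasets with
the published count structure.

The raw per-sample genotypes of that survey are deposited externally (YHRD
accessions YA004212-YA004216) and are not redistributed here; what this
module carries are the printed summary statistics — the irregular-allele
census counts, the forensic parameter counts and per-locus gene
diversities, and the 24-population pairwise Rst / permutation-P matrix —
which serve as worked-example inputs for the surrounding machinery.
"""

from __future__ import annotations

import io
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .alleles import AlleleValue, parse_allele
from .core import Haplotype, PopulationDataset
from .distance import DistanceMatrix
from .panel import DYS385_PAIR, YFILER_17
from .simulate import DEFAULT_FOUNDER

__all__ = [
    "POPULATION_SIZES",
    "variant_counts",
    "variant_count_dataset",
    "forensic_counts",
    "combined_gene_diversities",
    "rst_p_matrix",
    "dataset_with_count_profile",
]

#: Sample sizes of the five surveyed populations.
POPULATION_SIZES: Dict[str, int] = {
    "Arab": 102,
    "Kurdish": 104,
    "Syriac": 86,
    "Turkmen": 102,
    "Yazidi": 106,
}

_POPS = list(POPULATION_SIZES)

# (locus, variant, counts per population in _POPS order)
_VARIANT_ROWS: List[Tuple[str, str, Tuple[int, int, int, int, int]]] = [
    ("DYS19", "14,16", (0, 0, 0, 0, 1)),
    ("DYS389I", "10,13", (1, 0, 0, 0, 0)),
    ("DYS389I", "11,13", (0, 0, 1, 0, 0)),
    ("DYS389II", "30.3", (0, 0, 0, 0, 3)),
    ("DYS389II", "25,29", (0, 0, 1, 0, 0)),
    ("DYS392", "Null", (0, 0, 1, 0, 1)),
    ("DYS439", "8,11", (0, 0, 1, 0, 0)),
    ("DYS439", "11,12", (1, 0, 0, 0, 0)),
    ("DYS448", "Null", (0, 0, 1, 0, 1)),
    ("DYS448", "16.4", (0, 1, 0, 1, 0)),
    ("DYS448", "19,20", (0, 0, 0, 0, 5)),
    ("DYS448", "21,22", (0, 0, 0, 0, 3)),
    ("DYS456", "Null", (0, 0, 0, 1, 0)),
    ("DYS456", "12", (1, 1, 1, 0, 0)),
    ("DYS456", "19", (1, 0, 0, 0, 0)),
    ("DYS458", "12", (1, 0, 2, 0, 0)),
    ("DYS458", "17.2", (4, 2, 3, 1, 0)),
    ("DYS458", "18.2", (24, 9, 3, 6, 7)),
    ("DYS458", "19.2", (8, 5, 4, 2, 0)),
    ("DYS458", "20.2", (2, 1, 0, 4, 0)),
    ("DYS458", "21", (0, 1, 0, 1, 0)),
    ("DYS458", "21.2", (1, 0, 0, 0, 0)),
    ("Y_GATA_H4", "14", (0, 2, 0, 1, 0)),
    ("DYS385a/b", "15.2,17", (0, 2, 0, 0, 0)),
]


def variant_counts() -> pd.DataFrame:
    """Published per-population counts of every microvariant, off-ladder
    allele, bi-allelic pattern and null allele in the five-group survey."""
    rows = [
        {"locus": locus, "variant": variant, **dict(zip(_POPS, counts))}
        for locus, variant, counts in _VARIANT_ROWS
    ]
    return pd.DataFrame(rows)


def variant_count_dataset() -> List[PopulationDataset]:
    """Datasets with the surveyed sample sizes that carry exactly the
    published irregular-allele counts (all other calls are a fixed modal
    background).

    Only the irregular-call structure is faithful to the survey — haplotype
    frequencies are not — so this reconstruction is suitable for the
    variant census, which depends on those counts alone.
    """
    panel = YFILER_17
    a385, b385 = DYS385_PAIR
    background = {
        l: AlleleValue.integer(DEFAULT_FOUNDER[l]) for l in panel.loci
    }
    datasets = []
    for p_idx, pop in enumerate(_POPS):
        n = POPULATION_SIZES[pop]
        haps = [
            Haplotype(f"{pop}-{i+1:04d}", pop, dict(background))
            for i in range(n)
        ]
        cursor = 0
        for locus, variant, counts in _VARIANT_ROWS:
            for _ in range(counts[p_idx]):
                hap = haps[cursor]
                if locus == "DYS385a/b":
                    va, vb = (parse_allele(t) for t in variant.split(","))
                    haps[cursor] = hap.with_calls(**{a385: va, b385: vb})
                else:
                    haps[cursor] = hap.with_calls(
                        **{locus: parse_allele(variant, locus=locus)}
                    )
                cursor += 1
        datasets.append(PopulationDataset(pop, haps))
    return datasets


#: (n, number of different haplotypes, number of unique haplotypes)
_FORENSIC_COUNTS: Dict[str, Tuple[int, int, int]] = {
    "Combined": (500, 360, 280),
    "Arab": (102, 90, 80),
    "Kurdish": (104, 93, 84),
    "Syriac": (86, 48, 31),
    "Turkmen": (102, 86, 74),
    "Yazidi": (106, 50, 24),
}


def forensic_counts() -> Dict[str, Tuple[int, int, int]]:
    """Published (n, different, unique) haplotype counts per population."""
    return dict(_FORENSIC_COUNTS)


#: Published per-locus gene diversities of the combined 500-male dataset.
_COMBINED_GD: Dict[str, float] = {
    "DYS19": 0.6345,
    "DYS389I": 0.5964,
    "DYS389II": 0.7284,
    "DYS390": 0.7079,
    "DYS391": 0.4934,
    "DYS392": 0.5140,
    "DYS393": 0.5850,
    "DYS437": 0.5465,
    "DYS438": 0.6979,
    "DYS439": 0.6746,
    "DYS448": 0.6588,
    "DYS456": 0.6368,
    "DYS458": 0.8270,
    "DYS635": 0.7644,
    "Y_GATA_H4": 0.6582,
    "DYS385a/b": 0.9578,
}


def combined_gene_diversities() -> Dict[str, float]:
    return dict(_COMBINED_GD)


def dataset_with_count_profile(
    name: str, n: int, n_different: int, n_unique: int
) -> PopulationDataset:
    """A dataset realizing a given haplotype-multiplicity profile.

    Builds *n_different* distinct haplotypes of which *n_unique* occur once
    and the rest share the remaining n - n_unique copies (each repeated
    class gets at least two copies; leftovers are spread one at a time).
    UH and DC depend only on these counts, so the reconstruction computes
    them faithfully; haplotype diversity does not (it needs the survey's
    actual multiplicities) and must not be read off such a reconstruction.
    """
    n_repeated = n_different - n_unique
    n_copies = n - n_unique
    if n_repeated < 0 or (n_repeated > 0 and n_copies < 2 * n_repeated):
        raise ValueError("infeasible (n, different, unique) profile")
    mults = [1] * n_unique + [2] * n_repeated
    extra = n_copies - 2 * n_repeated
    i = 0
    while extra > 0 and n_repeated > 0:
        mults[n_unique + (i % n_repeated)] += 1
        extra -= 1
        i += 1
    panel = YFILER_17
    haps: List[Haplotype] = []
    sample = 0
    for idx, m in enumerate(mults):
        calls = {l: AlleleValue.integer(DEFAULT_FOUNDER[l]) for l in panel.loci}
        # distinct profile per class: spread an index over three loci
        calls["DYS390"] = AlleleValue.integer(10 + idx % 20)
        calls["DYS439"] = AlleleValue.integer(8 + (idx // 20) % 20)
        calls["DYS19"] = AlleleValue.integer(10 + (idx // 400) % 20)
        for _ in range(m):
            sample += 1
            haps.append(Haplotype(f"{name}-{sample:04d}", name, dict(calls)))
    return PopulationDataset(name, haps)


# ---------------------------------------------------------------------------
# 24-population pairwise Rst (below diagonal) / permutation P (above)
# ---------------------------------------------------------------------------

_RST_LABELS = [
    "Northern Iraq [Arab]",
    "Northern Iraq [Kurdish]",
    "Northern Iraq [Syriac]",
    "Northern Iraq [Turkmen]",
    "Northern Iraq [Yazidi]",
    "Afghanistan [Pathan]",
    "Albania [Albanian]",
    "Dhaka, Bangladesh [Bangladeshi]",
    "Bosnia and Herzegovina [Bosnian]",
    "Beijing, China [Han]",
    "Cyprus [Greek Cypriot]",
    "Cyprus [Turkish Cypriot]",
    "Upper Bavaria, Germany [German]",
    "Iran [Iranian]",
    "Iraq [Iraqi]",
    "Marche, Italy [Italian]",
    "Kuwait City, Kuwait [Arab]",
    "Beirut, Lebanon [Lebanese]",
    "Ulaanbaatar, Mongolia [Mongolian]",
    "Russian Federation [Russian]",
    "Tanzania [Tanzanian]",
    "Cukurova, Turkey [Turk]",
    "Marmara Region, Turkey [Turkish]",
    "Southeastern Anatolia, Turkey [Turkish]",
]

_RST_P_TEXT = """\
-\t0.0472\t0.0000\t0.0019\t0.0019\t0.0000\t0.0000\t0.0002\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0063\t0.0091\t0.0000\t0.2979\t0.0043\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0009
0.0137\t-\t0.0000\t0.0898\t0.0015\t0.0000\t0.0006\t0.0117\t0.0000\t0.0000\t0.0016\t0.0041\t0.0000\t0.0394\t0.1695\t0.0000\t0.0100\t0.0206\t0.0000\t0.0000\t0.0000\t0.0001\t0.0004\t0.0052
0.1005\t0.1025\t-\t0.0001\t0.0013\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0015\t0.0004\t0.0011\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0082\t0.0002\t0.0012
0.0344\t0.0091\t0.0762\t-\t0.0215\t0.0000\t0.0105\t0.0004\t0.0003\t0.0000\t0.0401\t0.1629\t0.0000\t0.1004\t0.2998\t0.0003\t0.0000\t0.0607\t0.0000\t0.0000\t0.0000\t0.0006\t0.0279\t0.0736
0.0369\t0.0394\t0.0545\t0.0205\t-\t0.0000\t0.0136\t0.0000\t0.0000\t0.0000\t0.0026\t0.0040\t0.0000\t0.1619\t0.0114\t0.0011\t0.0000\t0.0146\t0.0000\t0.0000\t0.0000\t0.0001\t0.0011\t0.0041
0.2257\t0.1966\t0.1162\t0.1999\t0.2054\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000
0.0892\t0.0560\t0.1004\t0.0314\t0.0289\t0.2313\t-\t0.0000\t0.0079\t0.0000\t0.0007\t0.0005\t0.0000\t0.0089\t0.0051\t0.0022\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0003
0.0416\t0.0157\t0.0971\t0.0342\t0.0605\t0.1460\t0.0765\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0008\t0.0032\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000
0.1604\t0.0878\t0.1925\t0.0622\t0.0955\t0.2636\t0.0355\t0.0800\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000
0.0898\t0.1023\t0.0836\t0.1220\t0.0882\t0.1304\t0.1410\t0.1012\t0.1880\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000
0.0493\t0.0259\t0.1188\t0.0097\t0.0238\t0.2778\t0.0321\t0.0686\t0.0721\t0.1471\t-\t0.2884\t0.0000\t0.0003\t0.0006\t0.0000\t0.0000\t0.0018\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0001
0.0428\t0.0181\t0.0960\t0.0031\t0.0185\t0.2384\t0.0325\t0.0521\t0.0651\t0.1307\t0.0004\t-\t0.0000\t0.0028\t0.0053\t0.0000\t0.0000\t0.0040\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0001
0.1965\t0.1575\t0.0798\t0.1247\t0.1212\t0.0934\t0.1056\t0.1141\t0.1358\t0.1455\t0.1793\t0.1513\t-\t0.0000\t0.0000\t0.0001\t0.0000\t0.0000\t0.0000\t0.0001\t0.0000\t0.0000\t0.0000\t0.0000
0.0266\t0.0142\t0.0385\t0.0083\t0.0055\t0.1519\t0.0321\t0.0292\t0.0865\t0.0668\t0.0305\t0.0192\t0.0944\t-\t0.4129\t0.0009\t0.0000\t0.0485\t0.0000\t0.0000\t0.0000\t0.0306\t0.1365\t0.1714
0.0259\t0.0046\t0.0506\t0.0011\t0.0233\t0.1509\t0.0337\t0.0183\t0.0653\t0.0899\t0.0252\t0.0148\t0.0967\t-0.0005\t-\t0.0001\t0.0000\t0.0275\t0.0000\t0.0000\t0.0000\t0.0226\t0.1719\t0.4068
0.1145\t0.0855\t0.0424\t0.0431\t0.0392\t0.1614\t0.0378\t0.0872\t0.0948\t0.1250\t0.0721\t0.0559\t0.0430\t0.0325\t0.0391\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0005\t0.0002\t0.0001
0.0011\t0.0148\t0.1285\t0.0352\t0.0577\t0.2616\t0.1055\t0.0545\t0.1586\t0.1193\t0.0446\t0.0415\t0.2249\t0.0443\t0.0365\t0.1298\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000
0.0182\t0.0114\t0.0718\t0.0065\t0.0124\t0.2222\t0.0467\t0.0457\t0.0940\t0.1082\t0.0099\t0.0070\t0.1547\t0.0075\t0.0087\t0.0636\t0.0237\t-\t0.0000\t0.0000\t0.0000\t0.0000\t0.0000\t0.0014
0.2592\t0.2222\t0.1434\t0.2010\t0.2042\t0.0986\t0.1973\t0.1633\t0.2045\t0.2004\t0.2652\t0.2318\t0.0618\t0.1724\t0.1610\t0.1454\t0.3023\t0.2349\t-\t0.0002\t0.0000\t0.0000\t0.0000\t0.0000
0.2563\t0.2089\t0.1399\t0.1801\t0.1938\t0.0827\t0.1736\t0.1414\t0.1775\t0.1872\t0.2451\t0.2104\t0.0257\t0.1540\t0.1423\t0.1146\t0.2850\t0.2126\t0.0221\t-\t0.0000\t0.0000\t0.0000\t0.0000
0.1707\t0.1842\t0.2984\t0.1833\t0.1768\t0.4160\t0.2158\t0.2467\t0.2774\t0.2969\t0.2070\t0.2026\t0.3675\t0.2108\t0.2169\t0.2677\t0.1903\t0.2302\t0.4383\t0.4327\t-\t0.0000\t0.0000\t0.0000
0.0662\t0.0462\t0.0194\t0.0266\t0.0385\t0.1087\t0.0658\t0.0441\t0.1022\t0.0915\t0.0671\t0.0480\t0.0615\t0.0102\t0.0105\t0.0231\t0.0826\t0.0378\t0.1316\t0.1052\t0.2928\t-\t0.1206\t0.0768
0.0578\t0.0310\t0.0364\t0.0107\t0.0259\t0.1382\t0.0417\t0.0347\t0.0658\t0.0983\t0.0407\t0.0270\t0.0696\t0.0039\t0.0024\t0.0220\t0.0698\t0.0233\t0.1429\t0.1137\t0.2785\t0.0023\t-\t0.1085
0.0354\t0.0237\t0.0397\t0.0086\t0.0261\t0.1556\t0.0551\t0.0384\t0.1002\t0.0952\t0.0390\t0.0266\t0.0983\t0.0040\t-0.0003\t0.0357\t0.0485\t0.0160\t0.1677\t0.1473\t0.2402\t0.0050\t0.0036\t-
"""


def rst_p_matrix() -> Tuple[DistanceMatrix, pd.DataFrame]:
    """The published 24-population pairwise matrix: Slatkin Rst values
    below the diagonal, permutation P values above (YHRD 16-locus AMOVA,
    10,000 permutations).

    Returns the symmetric Rst :class:`DistanceMatrix` (negative estimates
    kept as printed) and a DataFrame of P values.
    """
    raw = pd.read_csv(
        io.StringIO(_RST_P_TEXT), sep="\t", header=None, na_values=["-"]
    )
    k = len(_RST_LABELS)
    rst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i > j:
                rst[i, j] = rst[j, i] = raw.iat[i, j]
            elif i < j:
                pvals[i, j] = pvals[j, i] = raw.iat[i, j]
    matrix = DistanceMatrix(list(_RST_LABELS), rst)
    pdf = pd.DataFrame(pvals, index=_RST_LABELS, columns=_RST_LABELS)
    return matrix, pdf
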
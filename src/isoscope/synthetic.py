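"""Synthetic datasets: study-shaped fixtures and known-answer examples.

Everything the pipeline needs to be exercised without any download:

* multinomial population samples drawn from a deterministic haplotype pool
  (expected diversity computable in closed form from the frequencies),
* a study-shaped fixture - four mtDNA population samples of sizes
  40/59/48/46 with skewed haplotype frequencies calibrated so every
  realized haplotype diversity falls in the observed 0.88-0.98 span, plus
  three Y-STR populations of 50,
* small known-answer fixtures whose expected statistic values are computed
  here by independent direct-formula oracles and stored beside the data.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .datasets import SequenceDataset, SequenceRecord, StrDataset, StrRecord
from .errors import ValidationError
from .io import write_sequences, write_str_table

BASES = "ACGT"


def haplotype_pool(n_haplotypes: int, length: int = 333, seed: int = 7) -> list[str]:
    """Deterministic pool of aligned haplotypes, pairwise >= 2 differences.

    Haplotype 0 is a random reference; haplotype i (i >= 1) carries two
    private substitutions at sites 2(i-1) and 2(i-1)+1, so any two pool
    members differ at 2 (vs the reference) or 4 sites and collapsing is
    unambiguous.
    """
    if 2 * (n_haplotypes - 1) > length:
        raise ValidationError("pool too large for the alignment length")
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list(BASES), size=length))
    pool = [ref]
    for i in range(1, n_haplotypes):
        seq = list(ref)
        for site in (2 * (i - 1), 2 * (i - 1) + 1):
            current = seq[site]
            seq[site] = BASES[(BASES.index(current) + 1) % 4]
        pool.append("".join(seq))
    return pool


def generate_multinomial_population(freqs, pool, n: int,
                                    rng: np.random.Generator,
                                    population: str = "pop1",
                                    prefix: str = "s") -> SequenceDataset:
    """n records drawn i.i.d. from ``pool`` at the given frequencies."""
    freqs = np.asarray(freqs, dtype=np.float64)
    if len(pool) < freqs.size:
        raise ValidationError("haplotype pool smaller than the frequency vector")
    if not math.isclose(float(freqs.sum()), 1.0, abs_tol=1e-9):
        raise ValidationError("frequencies must sum to 1")
    draws = rng.choice(freqs.size, size=n, p=freqs)
    records = [
        SequenceRecord(f"{prefix}{i:04d}", population, pool[j])
        for i, j in enumerate(draws)
    ]
    return SequenceDataset(records, region_label="synthetic")


def _geometric_freqs(k: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(k)
    return w / w.sum()


def _realized_hd(sequences) -> float:
    _, counts = np.unique(sequences, return_counts=True)
    n = counts.sum()
    return float(n / (n - 1) * (1.0 - np.sum((counts / n) ** 2)))


#: Study-shaped sample sizes for the four mtDNA populations.
STUDY_MT_SIZES = (40, 59, 48, 46)
#: Three simulated-sink-sized Y-STR populations.
STUDY_STR_SIZES = (50, 50, 50)
#: Calibration band for realized per-population haplotype diversity.
HD_BAND = (0.88, 0.98)


def generate_study_fixture(seed: int = 0):
    """(SequenceDataset, StrDataset, manifest) shaped like the study data.

    Four mtDNA populations (sizes 40/59/48/46) drawn from overlapping
    windows of a shared haplotype pool with geometric frequency skew;
    each sample is redrawn until its realized haplotype diversity falls in
    ``HD_BAND``. Three Y-STR populations of 50 with population-shifted
    repeat profiles. The manifest records every generator parameter.
    """
    rng = np.random.default_rng(seed)
    pool = haplotype_pool(60, seed=7)
    ratios = (0.82, 0.78, 0.80, 0.81)
    offsets = (0, 12, 24, 36)
    k_per_pop = 22
    pop_names = [f"pop{i + 1}" for i in range(4)]
    mt_records = []
    realized = []
    for name, n, ratio, offset in zip(pop_names, STUDY_MT_SIZES, ratios, offsets):
        freqs = _geometric_freqs(k_per_pop, ratio)
        window = pool[offset : offset + k_per_pop]
        for attempt in range(500):
            draws = rng.choice(k_per_pop, size=n, p=freqs)
            seqs = [window[j] for j in draws]
            hd = _realized_hd(seqs)
            if HD_BAND[0] <= hd <= HD_BAND[1]:
                break
        else:
            raise RuntimeError(f"could not calibrate HD for {name}")
        realized.append(hd)
        mt_records.extend(
            SequenceRecord(f"{name}_{i:03d}", name, s) for i, s in enumerate(seqs)
        )
    mt = SequenceDataset(mt_records, region_label="synthetic-HVR")

    loci = ["DYS19", "DYS390", "DYS391", "DYS392", "DYS393"]
    base_alleles = np.array([14, 23, 10, 11, 13])
    str_records = []
    str_pops = [f"ypop{i + 1}" for i in range(3)]
    pop_shifts = [np.array(s) for s in ([0, 0, 0, 0, 0], [1, -1, 0, 1, 0], [-1, 1, 1, 0, -1])]
    for name, n, shift in zip(str_pops, STUDY_STR_SIZES, pop_shifts):
        for i in range(n):
            noise = rng.integers(-1, 2, size=len(loci))
            repeats = tuple(int(x) for x in base_alleles + shift + noise)
            str_records.append(StrRecord(f"{name}_{i:03d}", name, repeats))
    ystr = StrDataset(loci, str_records)

    manifest = {
        "seed": int(seed),
        "mt_sizes": list(STUDY_MT_SIZES),
        "mt_populations": pop_names,
        "geometric_ratios": list(ratios),
        "pool_offsets": list(offsets),
        "haplotypes_per_pop": k_per_pop,
        "hd_band": list(HD_BAND),
        "realized_hd": realized,
        "str_sizes": list(STUDY_STR_SIZES),
        "str_populations": str_pops,
        "str_loci": loci,
        "str_base_alleles": [int(x) for x in base_alleles],
        "str_pop_shifts": [[int(x) for x in s] for s in pop_shifts],
    }
    return mt, ystr, manifest


# ---------------------------------------------------------------------------
# Known-answer fixtures with independent direct-formula oracles


def _oracle_hd(counts) -> float:
    n = sum(counts)
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1 - sum_p2)


def _oracle_raggedness(freqs) -> float:
    x = list(freqs) + [0.0]
    return sum((x[i] - x[i - 1]) ** 2 for i in range(1, len(x)))


def _oracle_phist_two_pops(d2, labels):
    """Direct transcription of the one-level AMOVA sums of squares."""
    n = len(labels)
    ssd_total = sum(d2[i][j] for i in range(n) for j in range(n)) / (2.0 * n)
    groups = sorted(set(labels))
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        sizes.append(len(idx))
        ssd_within += sum(d2[i][j] for i in idx for j in idx) / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    sigma_w = ssd_within / df_within
    n_c = (n - sum(s**2 for s in sizes) / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


def _oracle_fs_n2(theta: float) -> float:
    s_prime = theta / (1.0 + theta)  # P(K=2) at n=2
    return math.log(s_prime / (1.0 - s_prime))


def generate_known_answer_fixtures(out_dir) -> dict:
    """Write the small worked examples used across module tests.

    Each fixture ships with its oracle-computed expected value in the
    manifest JSON; regeneration is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = "ACGTACGTAC"
    manifest: dict = {"fixtures": []}

    # 1. Nei HD on haplotype counts {3, 2, 1}
    hapA, hapB, hapC = ref, "TCGTACGTAC", "AGGTACGTAC"
    records = [
        SequenceRecord(f"h{i}", "pop1", s)
        for i, s in enumerate([hapA] * 3 + [hapB] * 2 + [hapC])
    ]
    ds = SequenceDataset(records, "fixture")
    write_sequences(ds, out_dir / "hd_321.fasta", out_dir / "hd_321.popmap.tsv")
    manifest["fixtures"].append(
        {
            "name": "hd_321",
            "files": ["hd_321.fasta", "hd_321.popmap.tsv"],
            "statistic": "haplotype_diversity",
            "expected": _oracle_hd([3, 2, 1]),
        }
    )

    # 2. Point-mass mismatch distribution (n=2, one difference) -> r = 2
    records = [
        SequenceRecord("m0", "pop1", ref),
        SequenceRecord("m1", "pop1", "CCGTACGTAC"),
    ]
    ds = SequenceDataset(records, "fixture")
    write_sequences(ds, out_dir / "mismatch_point.fasta",
                    out_dir / "mismatch_point.popmap.tsv")
    manifest["fixtures"].append(
        {
            "name": "mismatch_point",
            "files": ["mismatch_point.fasta", "mismatch_point.popmap.tsv"],
            "statistic": "raggedness",
            "expected": _oracle_raggedness([0.0, 1.0]),
        }
    )

    # 3. Two populations fixed for haplotypes one difference apart (n=5 each)
    hapD = "AAGTACGTAC"
    records = [SequenceRecord(f"a{i}", "popA", ref) for i in range(5)] + [
        SequenceRecord(f"b{i}", "popB", hapD) for i in range(5)
    ]
    ds = SequenceDataset(records, "fixture")
    write_sequences(ds, out_dir / "amova_fixed.fasta",
                    out_dir / "amova_fixed.popmap.tsv")
    d2 = [[0 if (i < 5) == (j < 5) else 1 for j in range(10)] for i in range(10)]
    labels = ["A"] * 5 + ["B"] * 5
    manifest["fixtures"].append(
        {
            "name": "amova_fixed",
            "files": ["amova_fixed.fasta", "amova_fixed.popmap.tsv"],
            "statistic": "phi_st",
            "expected": _oracle_phist_two_pops(d2, labels),
        }
    )

    # 4. n=2 Ewens case: theta_pi = 1, k = 2 -> Fs = 0
    records = [
        SequenceRecord("e0", "pop1", ref),
        SequenceRecord("e1", "pop1", "GCGTACGTAC"),
    ]
    ds = SequenceDataset(records, "fixture")
    write_sequences(ds, out_dir / "ewens_n2.fasta", out_dir / "ewens_n2.popmap.tsv")
    manifest["fixtures"].append(
        {
            "name": "ewens_n2",
            "files": ["ewens_n2.fasta", "ewens_n2.popmap.tsv"],
            "statistic": "fu_fs",
            "expected": _oracle_fs_n2(1.0),
        }
    )

    # 5. STR pair differing by 2 at one locus
    str_ds = StrDataset(
        ["DYS19", "DYS390"],
        [StrRecord("y0", "pop1", (14, 23)), StrRecord("y1", "pop1", (16, 23))],
    )
    write_str_table(str_ds, out_dir / "str_pair.tsv")
    manifest["fixtures"].append(
        {
            "name": "str_pair",
            "files": ["str_pair.tsv"],
            "statistic": "pairwise_difference",
            "expected": abs(14 - 16) + abs(23 - 23),
        }
    )

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def synthetic_panel(seed: int = 123, n_per_pop: int = 20,
                    length: int = 333) -> SequenceDataset:
    """Fixed 3-population synthetic panel (for subsample Fst scoring)."""
    rng = np.random.default_rng(seed)
    pool = haplotype_pool(30, length=length, seed=seed)
    records = []
    for p, offset in enumerate((0, 10, 20)):
        freqs = _geometric_freqs(10, 0.7)
        window = pool[offset : offset + 10]
        draws = rng.choice(10, size=n_per_pop, p=freqs)
        records.extend(
            SequenceRecord(f"panel{p + 1}_{i:03d}", f"panel{p + 1}", window[j])
            for i, j in enumerate(draws)
        )
    return SequenceDataset(records, region_label="synthetic-panel")
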
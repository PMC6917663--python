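"""Concordance filter vs brute force, bulk construction, interval arithmetic."""

import numpy as np
import pandas as pd
import pytest

from ltqtl import bsa
from ltqtl.bsa import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    BsaPolicy,
    Bulk,
    VariantTable,
    build_bulks,
    candidate_region,
    concordance_filter,
    extract_region,
    span_kb,
)


def brute_force_filter(variants, bulk_r, bulk_s, policy=None):
    """Naive per-SNP reimplementation of the concordance predicate."""
    policy = policy or BsaPolicy()
    passing = []
    for i in range(variants.n_snps):
        ok = True
        alleles = []
        for bulk in (bulk_r, bulk_s):
            calls = [
                int(variants.genotypes[i, variants.line_ids.index(l)])
                for l in bulk.line_ids
            ]
            if policy.ignore_het:
                calls = [c for c in calls if c != HET]
            elif any(c == HET for c in calls):
                ok = False
                break
            calls = [c for c in calls if c != MISSING]
            min_called = (
                policy.min_called if policy.min_called is not None else len(bulk.line_ids)
            )
            if len(calls) < max(min_called, 1):
                ok = False
                break
            if len(set(calls)) != 1 or calls[0] not in (HOM_REF, HOM_ALT):
                ok = False
                break
            alleles.append(calls[0])
        if ok and alleles[0] != alleles[1]:
            passing.append(i)
    return passing


def random_table(rng, n_snps=200, n_lines=10, missing=0.05, het=0.05):
    codes = rng.choice(
        [HOM_REF, HOM_ALT, HET, MISSING],
        p=[(1 - missing - het) / 2, (1 - missing - het) / 2, het, missing],
        size=(n_snps, n_lines),
    ).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10 * n_snps), size=n_snps, replace=False))
    refs = rng.choice(list("ACGT"), size=n_snps)
    alts = np.where(refs == "A", "G", "A")
    sites = pd.DataFrame({"chrom": "6", "pos": pos, "ref": refs, "alt": alts})
    lines = [f"L{i}" for i in range(n_lines)]
    return VariantTable(sites, lines, codes)


@pytest.fixture()
def bulks():
    return (
        Bulk("bulk_R", "resistant", [f"L{i}" for i in range(5)]),
        Bulk("bulk_S", "sensitive", [f"L{i}" for i in range(5, 10)]),
    )


@pytest.mark.parametrize("policy", [BsaPolicy(), BsaPolicy(min_called=3),
                                    BsaPolicy(ignore_het=True)])
def test_filter_matches_brute_force(rng, bulks, policy):
    for _ in range(20):
        vt = random_table(rng)
        res = concordance_filter(vt, *bulks, policy)
        expected = brute_force_filter(vt, *bulks, policy)
        assert list(np.flatnonzero(res.pass_mask)) == expected


def test_filter_symmetric_under_bulk_swap(rng, bulks):
    vt = random_table(rng)
    r1 = concordance_filter(vt, bulks[0], bulks[1])
    swapped = (
        Bulk("bulk_R", "resistant", bulks[1].line_ids),
        Bulk("bulk_S", "sensitive", bulks[0].line_ids),
    )
    r2 = concordance_filter(vt, *swapped)
    assert np.array_equal(r1.pass_mask, r2.pass_mask)


def test_filter_monotone_in_added_lines(rng):
    """A concordant extra line never removes a pass; a discordant one never adds."""
    vt = random_table(rng, n_lines=12)
    bulk_r = Bulk("bulk_R", "resistant", [f"L{i}" for i in range(5)])
    bulk_s = Bulk("bulk_S", "sensitive", [f"L{i}" for i in range(5, 10)])
    base = concordance_filter(vt, bulk_r, bulk_s)

    # L10 cloned from L0's calls -> concordant with bulk R wherever R passes
    vt_concordant = VariantTable(vt.sites.copy(), vt.line_ids, vt.genotypes.copy())
    vt_concordant.genotypes[:, 10] = vt.genotypes[:, 0]
    grown = concordance_filter(
        vt_concordant, Bulk("bulk_R", "resistant", bulk_r.line_ids + ["L10"]), bulk_s
    )
    assert set(np.flatnonzero(grown.pass_mask)) == set(np.flatnonzero(base.pass_mask))

    # L11 heterozygous everywhere -> discordant; nothing new can pass
    vt_discordant = VariantTable(vt.sites.copy(), vt.line_ids, vt.genotypes.copy())
    vt_discordant.genotypes[:, 11] = HET
    shrunk = concordance_filter(
        vt_discordant, Bulk("bulk_R", "resistant", bulk_r.line_ids + ["L11"]), bulk_s
    )
    assert set(np.flatnonzero(shrunk.pass_mask)) <= set(np.flatnonzero(base.pass_mask))


def test_all_lines_identical_nothing_passes(bulks):
    sites = pd.DataFrame(
        {"chrom": "6", "pos": [10, 20], "ref": ["A", "C"], "alt": ["G", "T"]}
    )
    vt = VariantTable(sites, [f"L{i}" for i in range(10)],
                      np.full((2, 10), HOM_ALT, dtype=np.int8))
    assert concordance_filter(vt, *bulks).n_passing == 0


def test_single_het_fails_snp_under_strict_policy(bulks):
    sites = pd.DataFrame({"chrom": "6", "pos": [10], "ref": ["A"], "alt": ["G"]})
    geno = np.array([[HOM_REF] * 5 + [HOM_ALT] * 5], dtype=np.int8)
    vt = VariantTable(sites, [f"L{i}" for i in range(10)], geno)
    assert concordance_filter(vt, *bulks).n_passing == 1
    geno_het = geno.copy()
    geno_het[0, 0] = HET
    vt2 = VariantTable(sites, [f"L{i}" for i in range(10)], geno_het)
    assert concordance_filter(vt2, *bulks).n_passing == 0


def test_missing_policy_relaxation(bulks):
    sites = pd.DataFrame({"chrom": "6", "pos": [10], "ref": ["A"], "alt": ["G"]})
    geno = np.array([[MISSING] + [HOM_REF] * 4 + [HOM_ALT] * 5], dtype=np.int8)
    vt = VariantTable(sites, [f"L{i}" for i in range(10)], geno)
    assert concordance_filter(vt, *bulks).n_passing == 0  # strict: missing fails
    relaxed = concordance_filter(vt, *bulks, BsaPolicy(min_called=4))
    assert relaxed.n_passing == 1


def test_empty_bulk_rejected(bulks):
    with pytest.raises(ValueError):
        Bulk("bulk_R", "resistant", [])


# ---------------------------------------------------------------------------
# bulk construction


def test_build_bulks_from_labels():
    labels = {f"R{i}": "resistant" for i in range(5)}
    labels.update({f"S{i}": "sensitive" for i in range(5)})
    br, bs = build_bulks(None, labels=labels)
    assert set(br.line_ids) == {f"R{i}" for i in range(5)}
    assert set(bs.line_ids) == {f"S{i}" for i in range(5)}


def test_build_bulks_by_ranking():
    pheno = {f"L{i}": float(i + 1) for i in range(10)}  # LTIIs 1..10
    br, bs = build_bulks(pheno, k=2)
    assert set(br.line_ids) == {"L0", "L1"}  # lowest injury = resistant
    assert set(bs.line_ids) == {"L9", "L8"}


def test_build_bulks_errors():
    with pytest.raises(ValueError):
        build_bulks({f"L{i}": float(i) for i in range(10)}, k=0)
    with pytest.raises(ValueError, match="ties"):
        build_bulks({"a": 1.0, "b": 1.0, "c": 1.0, "d": 2.0}, k=2)


# ---------------------------------------------------------------------------
# region extraction and interval arithmetic


def test_extract_region_boundaries_inclusive(rng, bulks):
    vt = random_table(rng, n_snps=100)
    lo, hi = int(vt.sites["pos"].iloc[30]), int(vt.sites["pos"].iloc[69])
    sub = extract_region(vt, "6", lo, hi)
    # oracle: linear scan
    expected = [
        int(p) for p in vt.sites["pos"] if lo <= p <= hi
    ]
    assert list(sub.sites["pos"]) == expected
    assert len(expected) == 40


def test_extract_region_empty_and_unknown_chrom(rng):
    vt = random_table(rng, n_snps=10)
    with pytest.warns(UserWarning, match="not present"):
        sub = extract_region(vt, "99", 1, 100)
    assert sub.n_snps == 0
    empty = VariantTable(
        pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]).astype(
            {"pos": int, "ref": str, "alt": str}
        ),
        ["L0"],
        np.empty((0, 1), dtype=np.int8),
    )
    assert extract_region(empty, "6", 1, 100).n_snps == 0


def test_candidate_region_spans():
    df = pd.DataFrame(
        {"chrom": "6", "pos": [20_779_616, 20_800_000, 20_821_620],
         "ref": "A", "alt": "G"}
    )
    chrom, lo, hi, kb = candidate_region(df)
    assert (lo, hi) == (20_779_616, 20_821_620)
    assert kb == 42
    single = candidate_region(df.iloc[[0]])
    assert single[3] == 0
    with pytest.raises(ValueError, match="no concordant"):
        candidate_region(df.iloc[[]])


def test_span_kb_truncates():
    assert span_kb(20_591_185, 21_186_690) == 595
    assert span_kb(20_779_616, 20_821_620) == 42
    assert span_kb(5, 5) == 0


def test_multiallelic_vcf_split(tmp_path):
    vcf = tmp_path / "multi.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=6,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL0\tL1\tL2\n"
        "6\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2\n"
        "6\t200\t.\tC\tCT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    vt = VariantTable.from_vcf(vcf)
    # indel skipped; multi-allelic SNP split into two biallelic rows
    assert vt.n_snps == 2
    assert list(vt.sites["alt"]) == ["G", "T"]
    g_alt1 = vt.genotypes[0]
    g_alt2 = vt.genotypes[1]
    assert list(g_alt1) == [HOM_REF, HOM_ALT, MISSING]  # T/T not a G call
    assert list(g_alt2) == [HOM_REF, MISSING, HOM_ALT]
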
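"""Locus calling: windowing, merging, annotation, set comparison, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteroscan.fpvd import FPVDTrack, fpvd_track
from heteroscan.loci import (
    Locus,
    annotate_loci,
    call_loci,
    compare_locus_sets,
    merge_intervals,
)
from heteroscan.synthetic import (
    PanelConfig,
    generate_hybrid_table,
    generate_panel,
    plant_heterosis_sites,
)

CHROMS = {"chr01": 5_000_000}


def make_track(sites, vclass="SNP"):
    """sites: list of (chrom, pos, fpvd) or (chrom, pos, fpvd, vclass)."""
    rows = []
    for entry in sites:
        chrom, pos, fpvd = entry[:3]
        vc = entry[3] if len(entry) > 3 else vclass
        rows.append(
            {"chrom": chrom, "pos": pos, "vclass": vc, "fpvd": fpvd,
             "n_informative": 20, "n_total": 20}
        )
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return FPVDTrack(label="t", table=table)


class TestCallLoci:
    def test_isolated_snp_gives_100kb_locus(self):
        track = make_track([("chr01", 1_000_000, 0.95)])
        (locus,) = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert (locus.start, locus.end) == (949_999, 1_049_999)
        assert locus.length == 100_000
        assert not locus.clipped

    def test_two_snps_60kb_apart_merge_to_160kb(self):
        track = make_track([("chr01", 1_000_000, 0.92), ("chr01", 1_060_000, 0.99)])
        (locus,) = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert locus.length == 160_000
        assert locus.n_snps_over_cutoff == 2
        assert locus.peak_fpvd == 0.99
        assert locus.peak_pos == 1_060_000

    def test_no_qualifying_site_gives_empty_list(self):
        track = make_track([("chr01", 1_000_000, 0.89)])
        assert call_loci(track, cutoff=0.9, chrom_lengths=CHROMS) == []

    def test_cutoff_comparison_non_strict(self):
        track = make_track([("chr01", 1_000_000, 0.9)])
        assert len(call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)) == 1

    def test_book_ended_windows_merge(self):
        track = make_track([("chr01", 1_000_000, 0.95), ("chr01", 1_100_000, 0.95)])
        (locus,) = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert locus.length == 200_000

    def test_edge_windows_clipped_and_flagged(self):
        track = make_track([("chr01", 20_000, 0.95)])
        (locus,) = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert locus.start == 0 and locus.length < 100_000
        assert locus.clipped

    def test_indels_counted_but_not_seeding(self):
        track = make_track(
            [("chr01", 1_000_000, 0.95, "SNP"), ("chr01", 1_010_000, 0.97, "indel"),
             ("chr01", 3_000_000, 0.99, "indel")]
        )
        loci = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert len(loci) == 1  # lone indel does not seed a locus
        assert loci[0].n_snps_over_cutoff == 1
        assert loci[0].n_indels_over_cutoff == 1

    def test_missing_chromosome_length_errors(self):
        track = make_track([("chrXX", 1_000_000, 0.95)])
        with pytest.raises(KeyError, match="chrXX"):
            call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)

    def test_undefined_sites_never_seed(self):
        track = make_track([("chr01", 1_000_000, float("nan"))])
        assert call_loci(track, cutoff=0.9, chrom_lengths=CHROMS) == []

    def test_every_qualifying_site_in_exactly_one_locus(self):
        rng = np.random.default_rng(8)
        sites = [("chr01", int(p), float(v)) for p, v in zip(
            np.sort(rng.choice(5_000_000, 300, replace=False)) + 1,
            rng.uniform(0.5, 1.0, 300),
        )]
        track = make_track(sites)
        loci = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        qualifying = [(c, p) for c, p, v in sites if v >= 0.9]
        for chrom, pos in qualifying:
            n_covering = sum(1 for l in loci if l.start <= pos - 1 < l.end)
            assert n_covering == 1
        # loci sorted, non-overlapping, each containing >= 1 qualifying site
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start
        for l in loci:
            assert any(l.start <= p - 1 < l.end for _, p in qualifying)

    def test_idempotent_recall(self):
        rng = np.random.default_rng(9)
        sites = [("chr01", int(p), float(v)) for p, v in zip(
            np.sort(rng.choice(5_000_000, 100, replace=False)) + 1,
            rng.uniform(0.8, 1.0, 100),
        )]
        track = make_track(sites)
        first = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        second = call_loci(track, cutoff=0.9, chrom_lengths=CHROMS)
        assert first == second


def naive_merge(intervals):
    """O(n^2) pairwise-merge oracle."""
    work = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                if a[0] <= b[1] and b[0] <= a[1]:  # overlap or book-ended
                    work[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del work[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in work)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        max_size=60,
    )
)
def test_merge_matches_naive_oracle(intervals):
    assert merge_intervals(intervals) == naive_merge(intervals)


def test_merge_matches_oracle_on_many_intervals():
    rng = np.random.default_rng(17)
    starts = rng.integers(0, 2_000_000, size=1000)
    intervals = [(int(s), int(s + rng.integers(1, 5_000))) for s in starts]
    assert merge_intervals(intervals) == naive_merge(intervals)


class TestAnnotate:
    GENES = pd.DataFrame(
        {
            "gene_id": ["inside", "abutting", "spanA", "spanB"],
            "chrom": ["chr01"] * 4,
            "start": [1_000, 5_000, 2_000, 4_000],
            "end": [2_000, 6_000, 3_000, 5_000],
        }
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    def test_overlap_semantics(self):
        loci = [Locus("chr01", 500, 5_000)]
        annotate_loci(loci, self.GENES)
        # half-open: gene starting exactly at locus end has zero overlap
        assert sorted(loci[0].gene_ids) == ["inside", "spanA", "spanB"]

    def test_locus_spanning_two_genes_lists_both(self):
        loci = [Locus("chr01", 2_500, 4_500)]
        annotate_loci(loci, self.GENES)
        assert sorted(loci[0].gene_ids) == ["spanA", "spanB"]


class TestCompareSets:
    def test_identical_sets_all_overlap(self):
        a = [Locus("chr01", 0, 100), Locus("chr01", 500, 700)]
        result = compare_locus_sets(a, list(a))
        assert result == {"a_total": 2, "b_total": 2, "a_overlapping": 2, "b_overlapping": 2}

    def test_disjoint_sets_zero_overlap(self):
        a = [Locus("chr01", 0, 100)]
        b = [Locus("chr01", 200, 300), Locus("chr02", 0, 100)]
        result = compare_locus_sets(a, b)
        assert result["a_overlapping"] == 0 and result["b_overlapping"] == 0

    def test_one_spanning_two(self):
        a = [Locus("chr01", 0, 1_000)]
        b = [Locus("chr01", 100, 200), Locus("chr01", 800, 900)]
        result = compare_locus_sets(a, b)
        assert result["a_overlapping"] == 1 and result["b_overlapping"] == 2


def test_planted_locus_recovery_exact():
    """With low background divergence every planted FPVD-1 site yields exactly
    its own 100-kb window and nothing else."""
    config = PanelConfig(
        seed=31, n_snps=2_000, n_indels=200, subgroup_divergence=0.05,
        missing_rate=0.0, residual_het_rate=0.0,
        n_accessions_per_role={"CMS": 20, "GMS": 5, "3R": 25, "2R": 5,
                               "3M": 5, "CR": 5, "GR": 5},
    )
    panel, accessions, truth = generate_panel(config)
    # a large hybrid set concentrates background FPVD well below the cut-off
    hybrids = generate_hybrid_table(accessions, 100, 0, seed=32)
    sites = [(c, p, 1.0) for c, p, _ in truth.heterosis_sites]
    panel = plant_heterosis_sites(panel, hybrids, sites, seed=33)
    track = fpvd_track(panel, hybrids)
    # the sterility/fertility site is itself a planted fixed difference
    # between the parents of every cross, so it seeds a window too
    planted = {(c, p) for c, p, _ in sites} | {truth.sterility_site}
    # precondition of the check: background (non-planted) FPVD below 0.8
    background = track.defined()[
        ~track.defined().apply(lambda r: (r["chrom"], r["pos"]) in planted, axis=1)
    ]
    assert background["fpvd"].max() < 0.8
    chrom_lengths = {f"chr{i + 1:02d}": config.chrom_length_bp for i in range(2)}
    loci = call_loci(track, cutoff=0.9, chrom_lengths=chrom_lengths)
    expected = []
    for chrom in sorted({c for c, _ in planted}):
        windows = [
            (max(0, p - 1 - 50_000), min(config.chrom_length_bp, p - 1 + 50_000))
            for c, p in planted
            if c == chrom
        ]
        expected.extend((chrom, s, e) for s, e in merge_intervals(windows))
    assert sorted((l.chrom, l.start, l.end) for l in loci) == sorted(expected)
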
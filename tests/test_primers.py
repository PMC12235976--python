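"""Primer constraint engine: nearest-neighbor Tm against a hand-summed
oracle, constraint satisfaction under fuzzing, screens, adapter tails."""

import math

import numpy as np
import pytest

from gbas.io import SequenceRecord, revcomp
from gbas.primers import (
    DUPLICATED_READS,
    MULTI_GENOME_HIT,
    NO_GENOME_HIT,
    P5_TAIL,
    P7_TAIL,
    PrimerConstraints,
    PrimerPair,
    attach_tails,
    count_read_matches,
    design_pairs,
    duplication_screen_reads,
    gc_fraction,
    genome_screen,
    melting_temperature,
    passes_single_primer,
)

# unified nearest-neighbor stack parameters: (kcal/mol, cal/(mol K))
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def hand_nn_tm(seq, na_mm=50.0, oligo_m=250e-9):
    """Independent oracle: sum stack ΔH/ΔS with terminal initiation terms and
    the entropy salt correction, Tm = ΔH / (ΔS + R ln C) − 273.15."""
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    return dh * 1000.0 / (ds + 1.987 * math.log(oligo_m)) - 273.15


class TestMeltingTemperature:
    def test_matches_hand_summed_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 23))))
            assert melting_temperature(seq) == pytest.approx(hand_nn_tm(seq), abs=1e-6)

    def test_duplex_symmetry(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(revcomp(seq)), abs=0.02
            )

    def test_monotone_in_gc_at_fixed_length(self):
        lo = "ATATATATATATGCGCATAT"  # 30% GC
        hi = "ATGCGCATGCGCATGCATAT"  # 50% GC
        assert melting_temperature(hi) > melting_temperature(lo)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACGTACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


def template_with_motif(rng, length=600, motif="ACGT" * 6, at=288):
    tpl = "".join(rng.choice(list("ACGT"), size=length))
    return tpl[:at] + motif + tpl[at + len(motif) :], (at, at + len(motif))


class TestDesignPairs:
    def test_ssr_template_yields_pairs_with_motif_near_one_end(self, rng):
        c = PrimerConstraints()
        tpl, span = template_with_motif(rng)
        pairs = design_pairs(tpl, motif_span=span)
        assert pairs
        for p in pairs[:50]:
            start, end = p.fwd_start, p.fwd_start + p.product_len
            assert start <= span[0] and span[1] <= end
            assert (span[1] - start <= c.motif_edge) or (end - span[0] <= c.motif_edge)

    def test_all_emitted_pairs_satisfy_constraints_independently(self, rng):
        c = PrimerConstraints()
        checked = 0
        for _ in range(15):
            tpl = "".join(rng.choice(list("ACGT"), size=560))
            for p in design_pairs(tpl)[:200]:
                for seq in (p.fwd, p.rev):
                    assert c.min_len <= len(seq) <= c.max_len
                    assert c.gc_min <= gc_fraction(seq) <= c.gc_max
                    for end in (seq[:2], seq[-2:]):
                        assert 1 <= sum(b in "GC" for b in end) <= 2
                    assert abs(hand_nn_tm(seq) - c.tm_opt) <= c.tm_band + 1e-9
                assert abs(p.tm_fwd - p.tm_rev) < c.max_tm_diff
                assert c.product_min <= p.product_len <= c.product_max
                # reverse primer actually matches the template
                assert (
                    revcomp(p.rev)
                    == tpl[p.fwd_start + p.product_len - len(p.rev) : p.fwd_start + p.product_len]
                )
                checked += 1
        assert checked > 100

    def test_product_length_window_enforced(self, rng):
        tpl = "".join(rng.choice(list("ACGT"), size=600))
        pairs = design_pairs(tpl)
        assert pairs
        best = pairs[0]
        # rebuild a template where the same primers can only give 480 bp
        pad = 480 - len(best.fwd) - len(best.rev)
        middle = "".join(rng.choice(list("ACGT"), size=pad))
        tpl480 = best.fwd + middle + revcomp(best.rev)
        windows = [(0, len(best.fwd)), (len(tpl480) - len(best.rev), len(tpl480))]
        assert design_pairs(tpl480, windows=windows) == []
        # at 450 bp the same construction is accepted
        pad = 450 - len(best.fwd) - len(best.rev)
        tpl450 = best.fwd + middle[:pad] + revcomp(best.rev)
        windows = [(0, len(best.fwd)), (len(tpl450) - len(best.rev), len(tpl450))]
        assert design_pairs(tpl450, windows=windows)

    def test_gc_clamp_excludes_at_rich_ends(self):
        assert not passes_single_primer("GCATCGCATCGCATCGAATT", PrimerConstraints())

    def test_windows_restrict_primer_footprints(self, rng):
        tpl = "".join(rng.choice(list("ACGT"), size=600))
        pairs = design_pairs(tpl, windows=[(0, 60), (520, 600)])
        for p in pairs:
            assert p.fwd_start + len(p.fwd) <= 60
            assert p.fwd_start + p.product_len - len(p.rev) >= 520

    def test_infeasible_template_gives_empty_list(self, rng):
        tpl = "".join(rng.choice(list("ACGT"), size=300))  # too short for 425 bp
        assert design_pairs(tpl) == []


class TestReadDuplicationScreen:
    def _pair(self, fwd, rev):
        return PrimerPair("L", fwd, rev, 55, 55, 0.5, 0.5, 450)

    def test_two_read_matches_flagged(self, rng):
        fwd = "ACGGCTAGCATCGGATCGCA"
        rev = "TGCCAGTCAGGATCCATGGA"
        reads = [
            SequenceRecord("r1", "T" * 30 + fwd + "G" * 30),
            SequenceRecord("r2", "A" * 10 + revcomp(fwd) + "C" * 50),
            SequenceRecord("r3", "".join(rng.choice(list("ACGT"), size=100))),
        ]
        pair = duplication_screen_reads(self._pair(fwd, rev), reads)
        assert DUPLICATED_READS in pair.screen_flags

    def test_single_and_zero_matches_pass(self, rng):
        fwd = "ACGGCTAGCATCGGATCGCA"
        rev = "TGCCAGTCAGGATCCATGGA"
        reads = [SequenceRecord("r1", "T" * 30 + fwd + "G" * 30)]
        assert duplication_screen_reads(self._pair(fwd, rev), reads).screen_flags == set()

    def test_match_counter_equals_bruteforce(self, rng):
        primer = "ACGGCTAGCATCGGATCGCA"
        reads = []
        for i in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            if i % 7 == 0:  # plant, sometimes with one substitution
                mutated = list(primer)
                if i % 14 == 0:
                    mutated[5] = "A" if mutated[5] != "A" else "C"
                seq = seq[:30] + "".join(mutated) + seq[30 + len(primer) :]
            reads.append(SequenceRecord(f"r{i}", seq))

        def oracle(primer, reads, k):
            total = 0
            for rec in reads:
                found = False
                for needle in (primer, revcomp(primer)):
                    for s in range(len(rec.seq) - len(needle) + 1):
                        mm = sum(
                            a != b for a, b in zip(rec.seq[s : s + len(needle)], needle)
                        )
                        if mm <= k:
                            found = True
                total += found
            return total

        for k in (0, 1, 2):
            assert count_read_matches(primer, reads, k) == oracle(primer, reads, k)


class TestGenomeScreen:
    @pytest.fixture
    def designed(self, rng):
        tpl = "".join(rng.choice(list("ACGT"), size=600))
        pairs = design_pairs(tpl)
        assert pairs
        return tpl, pairs[0]

    def test_unique_inward_hits_pass(self, designed, rng):
        tpl, pair = designed
        genome = {"c1": SequenceRecord("c1", "".join(rng.choice(list("ACGT"), size=500)) + tpl)}
        assert genome_screen(pair, genome).screen_flags == set()

    def test_duplicated_template_flags_multi_hit(self, designed, rng):
        tpl, pair = designed
        genome = {"c1": SequenceRecord("c1", tpl + "T" * 100 + tpl)}
        pair.screen_flags.clear()
        assert MULTI_GENOME_HIT in genome_screen(pair, genome).screen_flags

    def test_absent_forward_primer_flags_no_hit(self, designed, rng):
        tpl, pair = designed
        # genome holds only the 3' half: forward primer absent
        genome = {"c1": SequenceRecord("c1", tpl[300:])}
        pair.screen_flags.clear()
        assert NO_GENOME_HIT in genome_screen(pair, genome).screen_flags


class TestAdapterTails:
    def test_exact_tail_strings(self):
        pair = PrimerPair("L", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 55, 55, 0.5, 0.5, 450)
        attach_tails(pair)
        assert pair.tailed_fwd == "TCTTTCCCTACACGACGCTCTTCCGATCT" + "ACGTACGTACGTACGTACGT"
        assert pair.tailed_rev == "CTGGAGTTCAGACGTGTGCTCTTCCGATCT" + "TGCATGCATGCATGCATGCA"
        assert pair.tailed_fwd == P5_TAIL + pair.fwd
        assert pair.tailed_rev == P7_TAIL + pair.rev

    def test_double_tailing_is_error(self):
        pair = PrimerPair("L", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 55, 55, 0.5, 0.5, 450)
        attach_tails(pair)
        with pytest.raises(ValueError):
            attach_tails(pair)
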
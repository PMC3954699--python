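import numpy as np
import pytest

from sitescan.fixtures import ToyAtom, ToyStructureSpec, make_toy_structure
from sitescan.site_examples import (MissingAtomError, PatternSyntaxError,
                                    Provenance, SitePattern,
                                    build_training_set, collect_positives,
                                    deduplicate, extract_positive,
                                    load_site_table, match_pattern,
                                    parse_pattern, read_training_set,
                                    sample_negatives, validate_site_table,
                                    write_training_set)
from sitescan.structure import AtomRecord, ChainSequence

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Independent matching oracle: direct recursive element consumption, no regex.
# ---------------------------------------------------------------------------

def oracle_match_at(elements, seq, i):
    """Longest match length at offset i, or None. Pure recursion over
    elements, greedy on repeats (leftmost-longest)."""
    def consume(elem_idx, pos):
        if elem_idx == len(elements):
            return pos
        e = elements[elem_idx]
        for reps in range(e.max_repeat, e.min_repeat - 1, -1):
            ok = True
            p = pos
            for _ in range(reps):
                if p >= len(seq):
                    ok = False
                    break
                ch = seq[p]
                if e.kind == "literal" and ch != e.residues:
                    ok = False
                elif e.kind == "class" and ch not in e.residues:
                    ok = False
                elif e.kind == "exclusion" and ch in e.residues:
                    ok = False
                if not ok:
                    break
                p += 1
            if not ok:
                continue
            end = consume(elem_idx + 1, p)
            if end is not None:
                return end
        return None

    end = consume(0, i)
    return None if end is None else end - i


def _seq(letters, chain="A"):
    keys = tuple((i + 1, "") for i in range(len(letters)))
    return ChainSequence(chain_id=chain, sequence=letters, residue_keys=keys)


class TestParsePattern:
    def test_literals_only(self):
        p = parse_pattern("D-T-G")
        assert [e.kind for e in p.elements] == ["literal"] * 3
        assert [e.residues for e in p.elements] == ["D", "T", "G"]

    def test_class_and_fixed_repeat(self):
        p = parse_pattern("[LIVMFGAC]-x(2)-D")
        assert [e.kind for e in p.elements] == ["class", "any", "literal"]
        assert (p.elements[1].min_repeat, p.elements[1].max_repeat) == (2, 2)

    def test_exclusion_and_variable_repeat(self):
        p = parse_pattern("{P}-H-x(3,4)")
        assert p.elements[0].kind == "exclusion"
        assert p.elements[0].residues == "P"
        assert (p.elements[2].min_repeat, p.elements[2].max_repeat) == (3, 4)

    def test_anchors_and_terminator(self):
        p = parse_pattern("<A-x-G>.")
        assert p.anchored_start and p.anchored_end

    @pytest.mark.parametrize("bad", ["[AC-D", "{P-G", "A-x(0)", "A-x(3,2)",
                                     "A--G", "", "A-B(2"])
    def test_syntax_errors(self, bad):
        with pytest.raises(PatternSyntaxError):
            parse_pattern(bad)


class TestMatchPattern:
    def test_single_letter(self):
        pat = SitePattern("T", "A", 1, "ALA", "CB")
        matches = match_pattern(pat, _seq("A"))
        assert len(matches) == 1 and matches[0].start == 0

    def test_conserved_residue_resolution(self):
        pat = SitePattern("T", "D-x-G", 1, "ASP", "OD2")
        matches = match_pattern(pat, _seq("VDTGS"))
        assert len(matches) == 1
        assert matches[0].start == 1
        assert matches[0].conserved_residue_key == (2, "")

    def test_variable_repeat_overlapping_matches(self):
        pat = SitePattern("T", "H-x(1,2)-K", 1, "HIS", "NE2")
        matches = match_pattern(pat, _seq("HAKHAAK"))
        assert [m.start for m in matches] == [0, 3]
        assert [m.matched_span for m in matches] == ["HAK", "HAAK"]

    def test_conserved_mismatch_dropped_with_warning(self):
        pat = SitePattern("T", "D-x-G", 2, "ASP", "OD2")  # index 2 is not D
        with pytest.warns(UserWarning, match="does not match"):
            assert match_pattern(pat, _seq("DTG")) == []

    def test_agrees_with_recursive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(500):
            elements = []
            tokens = []
            for _ in range(rng.integers(1, 5)):
                kind = rng.choice(["literal", "class", "exclusion", "any"])
                if kind == "literal":
                    tokens.append(AA[rng.integers(len(AA))])
                elif kind == "class":
                    k = rng.integers(1, 4)
                    tokens.append("[" + "".join(
                        rng.choice(list(AA), size=k, replace=False)) + "]")
                elif kind == "exclusion":
                    tokens.append("{" + AA[rng.integers(len(AA))] + "}")
                else:
                    tok = "x"
                    if rng.random() < 0.5:
                        lo = int(rng.integers(1, 3))
                        hi = lo + int(rng.integers(0, 2))
                        tok += f"({lo},{hi})" if hi > lo else f"({lo})"
                    tokens.append(tok)
            text = "-".join(tokens)
            parsed = parse_pattern(text)
            seq = "".join(rng.choice(list("ACDGHK"), size=rng.integers(3, 12)))
            pat = SitePattern("T", text, 1, "XXX", "XX")  # unknown residue -> X
            got = {(m.start, m.matched_span)
                   for m in match_pattern(pat, _seq(seq))}
            want = set()
            for i in range(len(seq)):
                length = oracle_match_at(parsed.elements, seq, i)
                if length is not None and 0 < length:
                    want.add((i, seq[i:i + length]))
            assert got == want, f"pattern={text} seq={seq}"
            n_checked += 1
        assert n_checked == 500


class TestExtractPositive:
    def _structure(self):
        spec = ToyStructureSpec(atoms=[
            ToyAtom("N", "N", "ASP", "A", 25, 1.0, (1, 0, 0)),
            ToyAtom("O", "OD2", "ASP", "A", 25, 2.0, (0, 1, 0)),
            ToyAtom("C", "CA", "GLY", "A", 26, 3.0, (0, 0, 1)),
        ])
        return make_toy_structure(spec)

    def test_direct_lookup(self):
        from sitescan.site_examples import PatternMatch

        s = self._structure()
        pat = SitePattern("ASP_PROTEASE", "D-x", 1, "ASP", "OD2")
        m = PatternMatch("A", 0, "DG", (25, ""))
        np.testing.assert_allclose(extract_positive(s, m, pat), [0, 2.0, 0])

    def test_missing_atom_skipped_and_logged(self, caplog):
        from sitescan.site_examples import PatternMatch

        s = self._structure()
        pat = SitePattern("T", "G", 1, "GLY", "OD2")  # GLY has no OD2
        m = PatternMatch("A", 1, "G", (26, ""))
        with pytest.raises(MissingAtomError):
            extract_positive(s, m, pat)
        import logging
        with caplog.at_level(logging.WARNING, logger="sitescan.site_examples"):
            out = collect_positives(s, [m], pat)
        assert out == []
        assert "skipped" in caplog.text

    def test_bundled_table_asp_protease_row(self):
        sites = {s.name: s for s in load_site_table()}
        asp = sites["ASP_PROTEASE"]
        assert (asp.conserved_index, asp.residue_name,
                asp.functional_atom) == (4, "ASP", "OD2")
        assert len(sites) == 20

    def test_validation_flags_pa2_his(self):
        flagged = validate_site_table(load_site_table())
        assert any("PA2_HIS" in f and "SG" in f for f in flagged)
        assert not any("ASP_PROTEASE" in f for f in flagged)


class TestDeduplicate:
    def test_distinct_sequences_all_kept(self):
        entries = [("a", _seq("AAA"), 2.0), ("b", _seq("CCC"), 1.0),
                   ("c", _seq("DDD"), None)]
        assert len(deduplicate(entries)) == 3

    def test_best_resolution_wins(self):
        entries = [("worse", _seq("AAA"), 2.0), ("better", _seq("AAA"), 1.5)]
        assert deduplicate(entries)[0][0] == "better"

    def test_unknown_resolution_loses(self):
        entries = [("known", _seq("AAA"), 1.5), ("unknown", _seq("AAA"), None)]
        assert deduplicate(entries)[0][0] == "known"

    def test_tie_breaks_to_smallest_id(self):
        entries = [("zzz", _seq("AAA"), 1.5), ("aaa", _seq("AAA"), 1.5)]
        assert deduplicate(entries)[0][0] == "aaa"

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        entries = [(f"s{i}", _seq("ACD" if i % 3 else "GHK"), float(i % 4) or None)
                   for i in range(12)]
        base = deduplicate(entries)
        for _ in range(5):
            shuffled = list(entries)
            rng.shuffle(shuffled)
            assert deduplicate(shuffled) == base


def _pool_atom(i, residue="CYS", atom="SG"):
    return AtomRecord(
        serial=i, atom_name=atom, element="S" if atom == "SG" else "C",
        residue_name=residue, chain_id="A", residue_number=i,
        insertion_code="", coord=np.array([float(i), 0.0, 0.0]))


class TestSampleNegatives:
    def test_exact_draw_distinct(self):
        pool = [(f"s{i}", _pool_atom(i)) for i in range(200)]
        out = sample_negatives(pool, "CYS", "SG", 50, seed=1)
        assert len(out) == 50
        assert len({(sid, a.serial) for sid, a in out}) == 50

    def test_exhaustion_returns_all(self):
        pool = [(f"s{i}", _pool_atom(i)) for i in range(3)]
        for seed in (0, 1, 99):
            out = sample_negatives(pool, "CYS", "SG", 3, seed=seed)
            assert {a.serial for _, a in out} == {0, 1, 2}

    def test_filter_purity(self):
        pool = [(f"s{i}", _pool_atom(i, "CYS", "SG")) for i in range(50)]
        pool += [(f"t{i}", _pool_atom(i, "SER", "OG")) for i in range(50)]
        pool += [(f"u{i}", _pool_atom(i, "CYS", "CB")) for i in range(50)]
        out = sample_negatives(pool, "CYS", "SG", 30, seed=3)
        assert all(a.residue_name == "CYS" and a.atom_name == "SG"
                   for _, a in out)

    def test_seed_reproducible_and_seeds_differ(self):
        pool = [(f"s{i}", _pool_atom(i)) for i in range(1000)]
        a = sample_negatives(pool, "CYS", "SG", 100, seed=7)
        b = sample_negatives(pool, "CYS", "SG", 100, seed=7)
        c = sample_negatives(pool, "CYS", "SG", 100, seed=8)
        assert [x[1].serial for x in a] == [x[1].serial for x in b]
        assert [x[1].serial for x in a] != [x[1].serial for x in c]

    def test_short_pool_errors_unless_allowed(self):
        pool = [(f"s{i}", _pool_atom(i)) for i in range(5)]
        with pytest.raises(ValueError, match="5 atoms"):
            sample_negatives(pool, "CYS", "SG", 10, seed=0)
        with pytest.warns(UserWarning, match="smaller"):
            out = sample_negatives(pool, "CYS", "SG", 10, seed=0,
                                   allow_short=True)
        assert len(out) == 5


class TestBuildTrainingSet:
    def _examples(self, n, label_tag):
        spec = ToyStructureSpec(atoms=[
            ToyAtom("C", "CA", "ALA", "A", 1, 1.0, (1, 0, 0)),
            ToyAtom("O", "OD2", "ASP", "A", 2, 2.0, (0, 1, 0)),
        ])
        s = make_toy_structure(spec)
        return [
            (s, np.array([float(i), 0.0, 0.0]),
             Provenance(f"{label_tag}{i}", "A", i, "", "OD2"))
            for i in range(n)
        ]

    def test_counts_and_alignment(self):
        ts = build_training_set(self._examples(2, "p"), self._examples(3, "n"))
        assert ts.X.shape == (5, 480)
        assert ts.n_positive == 2 and ts.n_negative == 3
        assert len(ts.provenance) == 5

    def test_provenance_resolves(self):
        ts = build_training_set(self._examples(1, "p"), self._examples(1, "n"))
        assert ts.provenance[0].structure_id == "p0"
        assert ts.provenance[1].structure_id == "n0"

    def test_featurization_deterministic(self):
        a = build_training_set(self._examples(1, "p"), self._examples(1, "n"))
        b = build_training_set(self._examples(1, "p"), self._examples(1, "n"))
        np.testing.assert_array_equal(a.X, b.X)

    def test_tsv_round_trip(self, tmp_path):
        ts = build_training_set(self._examples(2, "p"), self._examples(2, "n"),
                                seed=9)
        path = tmp_path / "train.tsv"
        write_training_set(ts, str(path))
        again = read_training_set(str(path))
        np.testing.assert_allclose(again.X, ts.X, atol=1e-9)
        np.testing.assert_array_equal(again.y, ts.y)
        assert again.catalog_version == ts.catalog_version
        assert again.seed == 9
        assert again.provenance == ts.provenance
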
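import json

import numpy as np
import pytest

from pathcnn import corpus_io, synthetic
from pathcnn.corpus_io import (
    DependencyParse,
    EmbeddingFileRecord,
    Instance,
    ParseError,
    Token,
    ValidationError,
    read_instances,
    read_parses,
    read_word2vec,
    write_instances,
    write_parses,
    write_word2vec,
)

CONLL_FIG = """\
# sent_id = fig2
1\tAcanthamoeba\t2\tamod
2\tprofilin\t3\tnsubj
3\taffects\t0\troot
4\tthe\t6\tdet
5\tmechanical\t6\tamod
6\tproperties\t3\tdobj
7\tof\t6\tprep
8\tnon-filamentous\t9\tamod
9\tactin\t6\tprep-of
"""


class TestReadParses:
    def test_reads_worked_sentence(self, tmp_path):
        path = tmp_path / "p.conll"
        path.write_text(CONLL_FIG)
        parses = read_parses(path)
        assert len(parses) == 1
        assert parses[0].sentence_id == "fig2"
        assert len(parses[0]) == 9
        assert parses[0].form(3) == "affects"
        assert parses[0].tokens[8].deprel == "prep-of"

    def test_conllu_ten_column_layout(self, tmp_path):
        lines = ["1\tA\t_\t_\t_\t_\t2\tamod\t_\t_", "2\tB\t_\t_\t_\t_\t0\troot\t_\t_"]
        path = tmp_path / "p.conllu"
        path.write_text("\n".join(lines) + "\n")
        (parse,) = read_parses(path)
        assert [t.head for t in parse.tokens] == [2, 0]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.conll"
        path.write_text("")
        assert read_parses(path) == []

    def test_out_of_range_head_rejected(self, tmp_path):
        path = tmp_path / "bad.conll"
        path.write_text("1\ta\t99\tdep\n2\tb\t0\troot\n")
        with pytest.raises((ParseError, ValidationError), match="head"):
            read_parses(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.conll"
        path.write_text("1\ta\t0\troot\nnot a token line\n")
        with pytest.raises(ParseError, match=":2"):
            read_parses(path)

    def test_disconnected_parse_rejected(self):
        # two roots, no edge between {1} and {2}
        with pytest.raises(ValidationError, match="disconnected"):
            DependencyParse("x", (Token(1, "a", 0, "root"), Token(2, "b", 0, "root")))

    def test_round_trip_on_generated_corpus(self, tmp_path):
        parses, _ = synthetic.generate(synthetic.SynthConfig(n_instances=20, seed=5))
        path = tmp_path / "rt.conll"
        write_parses(parses, path)
        assert read_parses(path) == parses


class TestInstances:
    def test_round_trip(self, tmp_path, small_corpus):
        parses, instances = small_corpus
        path = tmp_path / "inst.jsonl"
        write_instances(instances, path)
        assert read_instances(path, parses) == instances

    def test_reads_worked_instance(self, tmp_path):
        path = tmp_path / "inst.jsonl"
        path.write_text(json.dumps({
            "instance_id": "i1", "sentence_id": "fig2",
            "e1": [2, 2], "e2": [9, 9], "label": 1,
        }) + "\n")
        (inst,) = read_instances(path)
        assert inst.e1_span == (2, 2) and inst.e2_span == (9, 9) and inst.label == 1

    @pytest.mark.parametrize(
        "record, err",
        [
            ({"instance_id": "i", "sentence_id": "s", "e1": [1, 1], "e2": [2, 2], "label": 2},
             "label"),
            ({"instance_id": "i", "sentence_id": "s", "e1": [1, 1], "e2": [1, 1], "label": 0},
             "identical"),
        ],
    )
    def test_invalid_instances_rejected(self, tmp_path, record, err):
        path = tmp_path / "inst.jsonl"
        path.write_text(json.dumps(record) + "\n")
        with pytest.raises(ValidationError, match=err):
            read_instances(path)

    def test_unknown_sentence_rejected(self, tmp_path, fig_sentence):
        parse, _ = fig_sentence
        path = tmp_path / "inst.jsonl"
        path.write_text(json.dumps({
            "instance_id": "i", "sentence_id": "nope",
            "e1": [1, 1], "e2": [2, 2], "label": 0,
        }) + "\n")
        with pytest.raises(ValidationError, match="unknown sentence"):
            read_instances(path, [parse])

    def test_span_outside_sentence_rejected(self, tmp_path, fig_sentence):
        parse, _ = fig_sentence
        path = tmp_path / "inst.jsonl"
        path.write_text(json.dumps({
            "instance_id": "i", "sentence_id": "fig2",
            "e1": [1, 1], "e2": [40, 41], "label": 0,
        }) + "\n")
        with pytest.raises(ValidationError, match="outside"):
            read_instances(path, [parse])


class TestWord2vec:
    @pytest.mark.parametrize("format", ["text", "binary"])
    def test_round_trip_identity(self, tmp_path, rng, format):
        # binary stores float32; start from float32 values so both formats
        # round-trip to full precision
        vecs = rng.normal(size=(5, 7)).astype(np.float32).astype(np.float64)
        records = [EmbeddingFileRecord(f"word{i}", vecs[i]) for i in range(5)]
        path = tmp_path / f"emb.{format}"
        write_word2vec(records, path, format)
        back = read_word2vec(path, format)
        assert [r.word for r in back] == [r.word for r in records]
        for a, b in zip(records, back):
            np.testing.assert_array_equal(a.vector, b.vector)

    def test_text_small_file(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("3 4\na 1 2 3 4\nb 5 6 7 8\nc 9 10 11 12\n")
        records = read_word2vec(path, "text")
        assert len(records) == 3 and all(len(r.vector) == 4 for r in records)

    def test_header_count_mismatch(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("5 2\na 1 2\nb 3 4\nc 5 6\nd 7 8\n")
        with pytest.raises(ParseError, match="declares 5"):
            read_word2vec(path, "text")

    def test_component_count_mismatch(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("1 3\na 1 2\n")
        with pytest.raises(ParseError, match="components"):
            read_word2vec(path, "text")

    def test_truncated_binary(self, tmp_path):
        path = tmp_path / "e.bin"
        path.write_bytes(b"1 4\nword " + b"\x00" * 7)
        with pytest.raises(ParseError, match="truncated"):
            read_word2vec(path, "binary")

    def test_duplicate_word_keeps_first(self, tmp_path, caplog):
        path = tmp_path / "e.txt"
        path.write_text("2 2\na 1 2\na 3 4\n")
        records = read_word2vec(path, "text")
        assert len(records) == 1
        np.testing.assert_array_equal(records[0].vector, [1.0, 2.0])
        assert any("duplicate" in r.message for r in caplog.records)


class TestModelContainer:
    @pytest.fixture
    def fitted(self, small_corpus):
        from pathcnn import PathCNNClassifier
        from pathcnn.sdp import extract_sequences

        parses, instances = small_corpus
        seqs = extract_sequences(parses, instances)
        clf = PathCNNClassifier(n_fixed=13, dim=8, n_filters=4, hidden=6, epochs=2, seed=9)
        clf.fit([s.tokens for s in seqs], [i.label for i in instances])
        return clf, [s.tokens for s in seqs]

    def test_round_trip_bit_exact(self, tmp_path, fitted):
        clf, X = fitted
        path = tmp_path / "model.json"
        corpus_io.save_model(clf, path)
        back = corpus_io.load_model(path)
        for name, arr in clf.params_.arrays().items():
            np.testing.assert_array_equal(arr, back.params_.arrays()[name])
        np.testing.assert_array_equal(clf.tables_[0].D, back.tables_[0].D)
        np.testing.assert_array_equal(clf.predict_proba(X[:5]), back.predict_proba(X[:5]))

    def test_shape_tamper_rejected(self, tmp_path, fitted):
        clf, _ = fitted
        path = tmp_path / "model.json"
        corpus_io.save_model(clf, path)
        payload = json.loads(path.read_text())
        payload["model"]["hyperparams"]["n_filters"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="shape"):
            corpus_io.load_model(path)

    def test_version_mismatch_rejected(self, tmp_path, fitted):
        clf, _ = fitted
        path = tmp_path / "model.json"
        corpus_io.save_model(clf, path)
        payload = json.loads(path.read_text())
        payload["version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="version"):
            corpus_io.load_model(path)
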
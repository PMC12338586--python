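import json

import numpy as np
import pytest
from shapely.geometry import Polygon

import ftuscope as ft
from ftuscope.annotation_io import (
    AnnotationType,
    FTUAnnotation,
    append_action_log,
    new_uuid,
    read_action_log,
)
from ftuscope.errors import GeometryError, SchemaError


def _square(x0=0, y0=0, side=10):
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


def _ann(vocab, cid=1, atype=AnnotationType.AUTO, rng=None, **kw):
    return FTUAnnotation(
        uuid=new_uuid(rng),
        class_id=cid,
        class_name=vocab.id_to_name(cid),
        annotation_type=atype,
        geometry=kw.pop("geometry", _square()),
        **kw,
    )


class TestGeoJSONRoundTrip:
    def test_round_trip_preserves_every_field(self, tmp_path, prostate, rng):
        annotations = [
            _ann(prostate, cid=1, rng=rng, metadata={"note": "lumen visible"}),
            _ann(
                prostate,
                cid=5,
                atype=AnnotationType.AUTO_EDITED,
                rng=rng,
                geometry=_square(20, 20, 7),
                flagged_for_review=True,
            ),
            _ann(prostate, cid=17, atype=AnnotationType.MANUAL, rng=rng,
                 geometry=Polygon([(40, 40), (55, 42), (50, 58), (41, 50)])),
        ]
        aset = ft.AnnotationSet("img-1", annotations, "prostate")
        p = tmp_path / "a.geojson"
        ft.write_geojson(aset, p)
        back = ft.read_geojson(p, prostate)
        assert back.image_id == "img-1"
        assert back.vocabulary_ref == "prostate"
        assert back.annotations == annotations

    def test_write_read_write_is_byte_identical(self, tmp_path, prostate, rng):
        aset = ft.AnnotationSet(
            "img", [_ann(prostate, cid=c, rng=rng, geometry=_square(12 * c, 0, 9))
                    for c in (1, 2, 3)], "prostate",
        )
        p1, p2 = tmp_path / "a.geojson", tmp_path / "b.geojson"
        ft.write_geojson(aset, p1)
        ft.write_geojson(ft.read_geojson(p1, prostate), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cardinality_conserved(self, tmp_path, prostate, rng):
        for n in (0, 3):
            aset = ft.AnnotationSet(
                "img", [_ann(prostate, rng=rng, geometry=_square(12 * i, 0, 8))
                        for i in range(n)],
            )
            p = tmp_path / f"n{n}.geojson"
            ft.write_geojson(aset, p)
            doc = json.loads(p.read_text())
            assert len(doc["features"]) == n
            assert len(ft.read_geojson(p, prostate)) == n

    def test_unknown_annotation_type_rejected(self, tmp_path, prostate, rng):
        p = tmp_path / "a.geojson"
        ft.write_geojson(ft.AnnotationSet("i", [_ann(prostate, rng=rng)]), p)
        doc = json.loads(p.read_text())
        doc["features"][0]["properties"]["miroscope"]["annotation_type"] = "semi_auto"
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="semi_auto"):
            ft.read_geojson(p, prostate)

    def test_missing_required_property_cites_feature_index(self, tmp_path, prostate, rng):
        p = tmp_path / "a.geojson"
        ft.write_geojson(
            ft.AnnotationSet("i", [_ann(prostate, rng=rng),
                                   _ann(prostate, rng=rng, geometry=_square(20, 0, 8))]), p
        )
        doc = json.loads(p.read_text())
        del doc["features"][1]["properties"]["miroscope"]["uuid"]
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="feature 1"):
            ft.read_geojson(p, prostate)

    def test_unresolvable_class_id_raises(self, tmp_path, prostate, rng):
        p = tmp_path / "a.geojson"
        ft.write_geojson(ft.AnnotationSet("i", [_ann(prostate, rng=rng)]), p)
        doc = json.loads(p.read_text())
        body = doc["features"][0]["properties"]["miroscope"]
        body["class_id"] = 99
        del body["class_name"]
        p.write_text(json.dumps(doc))
        from ftuscope.errors import VocabularyError

        with pytest.raises(VocabularyError, match="99"):
            ft.read_geojson(p, prostate)

    def test_flat_properties_dialect_accepted(self, tmp_path, prostate, rng):
        a = _ann(prostate, rng=rng)
        doc = {
            "type": "FeatureCollection",
            "features": [{
                "type": "Feature",
                "geometry": {"type": "Polygon",
                             "coordinates": [list(map(list, a.geometry.exterior.coords))]},
                "properties": {"uuid": a.uuid, "class_id": 1,
                               "annotation_type": "auto_checked"},
            }],
        }
        p = tmp_path / "flat.geojson"
        p.write_text(json.dumps(doc))
        back = ft.read_geojson(p, prostate)
        assert back.annotations[0].annotation_type is AnnotationType.AUTO_CHECKED

    def test_duplicate_uuid_refused(self, tmp_path, prostate, rng):
        a = _ann(prostate, rng=rng)
        with pytest.raises(SchemaError, match=a.uuid):
            ft.AnnotationSet("i", [a, a])


class TestProvenanceTransitions:
    def test_confirm_promotes_auto_to_auto_checked(self, prostate, rng):
        a = _ann(prostate, rng=rng)
        out = ft.apply_curation_action(a, "confirm")
        assert out.annotation_type is AnnotationType.AUTO_CHECKED
        assert out.uuid == a.uuid

    @pytest.mark.parametrize("start", [AnnotationType.AUTO, AnnotationType.AUTO_CHECKED])
    def test_any_edit_yields_auto_edited(self, prostate, rng, start):
        a = _ann(prostate, atype=start, rng=rng)
        g = ft.apply_curation_action(a, "edit_geometry", geometry=_square(2, 2, 8))
        c = ft.apply_curation_action(a, "edit_class", class_id=4, vocabulary=prostate)
        assert g.annotation_type is AnnotationType.AUTO_EDITED
        assert c.annotation_type is AnnotationType.AUTO_EDITED
        assert c.class_name == "Gleason pattern 3"
        assert g.uuid == c.uuid == a.uuid

    @pytest.mark.parametrize("terminal", [AnnotationType.MANUAL, AnnotationType.AUTO_EDITED])
    def test_terminal_types_absorb_confirm_and_edit(self, prostate, rng, terminal):
        a = _ann(prostate, atype=terminal, rng=rng)
        assert ft.apply_curation_action(a, "confirm").annotation_type is terminal
        out = ft.apply_curation_action(a, "edit_geometry", geometry=_square(1, 1, 9))
        assert out.annotation_type is terminal

    def test_create_manual(self, prostate, rng):
        a = ft.create_manual(_square(), 4, prostate, rng=rng)
        assert a.annotation_type is AnnotationType.MANUAL
        assert a.class_name == "Gleason pattern 3"

    def test_invalid_replacement_polygon_raises(self, prostate, rng):
        a = _ann(prostate, rng=rng)
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(GeometryError):
            ft.apply_curation_action(a, "edit_geometry", geometry=bowtie)


class TestFlagForReview:
    def test_flag_set_clear_and_idempotent(self, prostate, rng):
        a = _ann(prostate, rng=rng)
        once = ft.flag_for_review(a, True)
        twice = ft.flag_for_review(once, True)
        assert once.flagged_for_review and twice.flagged_for_review
        assert not ft.flag_for_review(twice, False).flagged_for_review

    def test_flag_changes_nothing_else(self, prostate, rng):
        a = _ann(prostate, rng=rng)
        f = ft.flag_for_review(a, True)
        assert (f.uuid, f.class_id, f.annotation_type, f.metadata) == (
            a.uuid, a.class_id, a.annotation_type, a.metadata)


def test_geometry_validation():
    with pytest.raises(GeometryError):
        FTUAnnotation(
            uuid=new_uuid(np.random.default_rng(0)), class_id=1, class_name="x",
            annotation_type=AnnotationType.AUTO,
            geometry=Polygon([(0, 0), (10, 10), (10, 0), (0, 10)]),  # self-crossing
        )


def test_action_log_round_trip(tmp_path):
    p = tmp_path / "log.jsonl"
    recs = [
        {"timestamp": "2025-01-01T00:00:00+00:00", "image_id": "i", "uuid": "u1",
         "action": "confirm", "from_type": "auto", "to_type": "auto_checked"},
        {"timestamp": "2025-01-01T00:00:05+00:00", "image_id": "i", "uuid": "u2",
         "action": "edit_geometry", "from_type": "auto", "to_type": "auto_edited"},
    ]
    append_action_log(p, recs)
    assert read_action_log(p) == recs
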
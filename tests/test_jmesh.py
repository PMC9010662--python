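"""JMesh/JNIfTI I/O: dialect equivalence, round-trips, validation."""

import base64
import json
import zlib

import numpy as np
import pytest

from tetmc import jmesh


def _annotate(arr, compress=False):
    """Independent JData typed-array encoder used as the oracle."""
    arr = np.asarray(arr)
    jtype = "double" if arr.dtype.kind == "f" else "int32"
    arr = arr.astype(np.float64 if jtype == "double" else np.int32)
    out = {"_ArrayType_": jtype, "_ArraySize_": list(arr.shape)}
    if compress:
        out["_ArrayZipType_"] = "zlib"
        out["_ArrayZipSize_"] = list(arr.shape)
        out["_ArrayZipData_"] = base64.b64encode(
            zlib.compress(arr.ravel(order="C").tobytes())).decode()
    else:
        out["_ArrayData_"] = arr.ravel(order="C").tolist()
    return out


class TestReadMeshDocument:
    def test_plain_unit_cube_counts(self, cube_doc_text):
        doc = jmesh.read_mesh_document(cube_doc_text)
        assert doc.vertices.shape == (8, 3)
        assert doc.triangles.shape == (12, 3)
        assert doc.tetrahedra.shape == (6, 4)
        # 1-based file indices became 0-based in memory
        assert doc.tetrahedra.min() == 0
        assert doc.tetrahedra.max() == 7

    def test_vertex_only_document(self):
        doc = jmesh.read_mesh_document(
            json.dumps({"MeshVertex3": [[0, 0, 0], [1, 0, 0], [0, 1, 0]]}))
        assert doc.vertices.shape == (3, 3)
        assert doc.triangles.size == 0
        assert doc.tetrahedra.size == 0

    @pytest.mark.parametrize("compress", [False, True],
                             ids=["annotated", "compressed"])
    def test_dialects_decode_identically(self, cube_doc_text, compress):
        plain = jmesh.read_mesh_document(cube_doc_text)
        raw = json.loads(cube_doc_text)
        encoded = json.dumps(
            {k: _annotate(v, compress) for k, v in raw.items()})
        other = jmesh.read_mesh_document(encoded)
        np.testing.assert_array_equal(plain.vertices, other.vertices)
        np.testing.assert_array_equal(plain.triangles, other.triangles)
        np.testing.assert_array_equal(plain.tetrahedra, other.tetrahedra)

    def test_malformed_json_reports_offset(self):
        with pytest.raises(jmesh.JMeshError, match="byte offset"):
            jmesh.read_mesh_document('{"MeshVertex3": [[0,0,0], }')

    def test_size_tag_payload_mismatch(self):
        bad = json.dumps({"MeshVertex3": {
            "_ArrayType_": "double", "_ArraySize_": [4, 3],
            "_ArrayData_": [0.0] * 9}})
        with pytest.raises(jmesh.JMeshError, match="size tag"):
            jmesh.read_mesh_document(bad)

    def test_index_out_of_range(self):
        bad = json.dumps({"MeshVertex3": [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                          "MeshTri3": [[1, 2, 9]]})
        with pytest.raises(jmesh.JMeshError, match="outside"):
            jmesh.read_mesh_document(bad)

    def test_unknown_keys_preserved_in_metadata(self, cube_doc_text):
        raw = json.loads(cube_doc_text)
        raw["CustomAnnotation"] = {"answer": 42}
        doc = jmesh.read_mesh_document(json.dumps(raw))
        assert doc.metadata["CustomAnnotation"] == {"answer": 42}


class TestWriteMeshDocument:
    @pytest.mark.parametrize("dialect", ["plain", "annotated", "compressed"])
    def test_round_trip(self, cube_doc_text, tmp_path, dialect):
        doc = jmesh.read_mesh_document(cube_doc_text)
        doc.tet_labels = np.array([1, 1, 2, 2, 3, 3])
        doc.node_data = np.linspace(0.0, 1.0, 8)
        path = tmp_path / f"cube_{dialect}.jmsh"
        jmesh.write_mesh_document(doc, path, dialect=dialect)
        back = jmesh.read_mesh_document(path)
        np.testing.assert_array_equal(back.triangles, doc.triangles)
        np.testing.assert_array_equal(back.tetrahedra, doc.tetrahedra)
        np.testing.assert_array_equal(back.tet_labels, doc.tet_labels)
        np.testing.assert_allclose(back.vertices, doc.vertices, rtol=0)
        np.testing.assert_allclose(back.node_data, doc.node_data, rtol=0)

    def test_written_indices_are_one_based(self, cube_doc_text, tmp_path):
        doc = jmesh.read_mesh_document(cube_doc_text)
        path = tmp_path / "cube.jmsh"
        jmesh.write_mesh_document(doc, path)
        raw = json.loads(path.read_text())
        assert np.asarray(raw["MeshTet4"]).min() == 1

    def test_refuses_nonfinite_coordinates(self, tmp_path):
        doc = jmesh.MeshDocument(
            vertices=np.array([[0.0, 0.0, np.nan]]),
            triangles=np.zeros((0, 3), int), tetrahedra=np.zeros((0, 4), int))
        with pytest.raises(jmesh.JMeshError, match="non-finite"):
            jmesh.write_mesh_document(doc, tmp_path / "bad.jmsh")


class TestVolumes:
    @pytest.fixture
    def labels_4x4x4(self):
        vox = np.zeros((4, 4, 4), dtype=np.int16)
        vox[1:3, 1:3, 1:3] = 1
        return vox

    def test_read_nii(self, labels_4x4x4, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(labels_4x4x4, affine=np.eye(4))
        path = tmp_path / "vol.nii"
        nib.save(img, path)
        vol = jmesh.read_volume(path)
        assert vol.voxel_size == 1.0
        np.testing.assert_array_equal(vol.voxels, labels_4x4x4)

    def test_jnii_matches_nii(self, labels_4x4x4, tmp_path):
        import nibabel as nib

        nii = tmp_path / "vol.nii"
        nib.save(nib.Nifti1Image(labels_4x4x4, affine=np.eye(4)), nii)
        jnii = tmp_path / "vol.jnii"
        jmesh.write_jnii(jmesh.LabeledVolume(labels_4x4x4, 1.0), jnii)
        a = jmesh.read_volume(nii)
        b = jmesh.read_volume(jnii)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert a.voxel_size == b.voxel_size

    def test_jnii_compressed_payload(self, labels_4x4x4, tmp_path):
        path = tmp_path / "vol.jnii"
        jmesh.write_jnii(jmesh.LabeledVolume(labels_4x4x4, 0.8), path,
                         dialect="compressed")
        vol = jmesh.read_volume(path)
        assert vol.voxel_size == pytest.approx(0.8)
        np.testing.assert_array_equal(vol.voxels, labels_4x4x4)

    def test_rejects_float_volume(self, tmp_path):
        import nibabel as nib

        data = np.random.default_rng(0).random((3, 3, 3))
        path = tmp_path / "float.nii"
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
        with pytest.raises(jmesh.JMeshError, match="integer"):
            jmesh.read_volume(path)

    def test_rejects_anisotropic_voxels(self, labels_4x4x4, tmp_path):
        import nibabel as nib

        aff = np.diag([1.0, 1.0, 2.0, 1.0])
        path = tmp_path / "aniso.nii"
        nib.save(nib.Nifti1Image(labels_4x4x4, affine=aff), path)
        with pytest.raises(jmesh.JMeshError, match="anisotropic"):
            jmesh.read_volume(path)

    def test_rejects_unknown_format(self, tmp_path):
        path = tmp_path / "vol.mat"
        path.write_bytes(b"\x00")
        with pytest.raises(jmesh.JMeshError, match="accepted formats"):
            jmesh.read_volume(path)


class TestFluenceOutput:
    def test_round_trip_and_log10(self, cube_mesh, tmp_path):
        fl = np.zeros(8)
        fl[3] = 100.0
        path = tmp_path / "fluence.jmsh"
        jmesh.write_fluence(cube_mesh, fl, path, floor=1e-12)
        back = jmesh.read_mesh_document(path)
        np.testing.assert_allclose(back.node_data, fl, rtol=0)
        disp = np.asarray(back.metadata["MeshNodeValLog10"]["_ArrayData_"]
                          if isinstance(back.metadata["MeshNodeValLog10"],
                                        dict)
                          else back.metadata["MeshNodeValLog10"])
        assert disp.reshape(-1)[3] == pytest.approx(2.0)

    def test_all_zero_fluence_hits_floor(self, cube_mesh, tmp_path):
        path = tmp_path / "zero.jmsh"
        jmesh.write_fluence(cube_mesh, np.zeros(8), path, floor=1e-12)
        back = jmesh.read_mesh_document(path)
        disp = np.asarray(back.metadata["MeshNodeValLog10"])
        assert np.all(disp.reshape(-1) == -12.0)

    def test_length_mismatch(self, cube_mesh, tmp_path):
        with pytest.raises(jmesh.JMeshError, match="node count"):
            jmesh.write_fluence(cube_mesh, np.zeros(5), tmp_path / "x.jmsh")


def test_off_import(tmp_path):
    path = tmp_path / "tri.off"
    path.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
    verts, faces = jmesh.read_off(path)
    assert verts.shape == (3, 3)
    np.testing.assert_array_equal(faces, [[0, 1, 2]])
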
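"""HDF5 / TIFF persistence for images, sinograms, datasets and checkpoints.

Images and sinograms are float32 HDF5 datasets with the acquisition
geometry serialized as attributes; images can also be exported as TIFF.
Phantom-pair datasets use one group per pair (/pair000/clean, /corrupted,
/metal_mask, /sino_corrupted) plus a JSON manifest of seeds and phantom
parameters.  Model checkpoints are single ``.npz`` archives holding every
parameter array (in the module's deterministic iteration order) plus a JSON
config header sufficient to rebuild the architecture.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import tifffile

from .geometry import FanBeamGeometry, Image2D, Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_image_tiff",
    "load_image_tiff",
    "save_pairs",
    "load_pairs",
    "save_checkpoint",
    "load_checkpoint",
]


def save_image(path: str, image: Image2D, name: str = "image") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=image.values.astype(np.float32))
        ds.attrs["pixel_size_mm"] = image.pixel_size


def load_image(path: str, name: str = "image") -> Image2D:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return Image2D(ds[()].astype(np.float64), float(ds.attrs["pixel_size_mm"]))


def save_sinogram(path: str, sino: Sinogram, name: str = "sinogram") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=sino.values.astype(np.float32))
        for key, val in sino.geometry.to_attrs().items():
            ds.attrs[key] = val


def load_sinogram(path: str, name: str = "sinogram") -> Sinogram:
    with h5py.File(path, "r") as f:
        ds = f[name]
        geo = FanBeamGeometry.from_attrs(dict(ds.attrs))
        return Sinogram(ds[()].astype(np.float64), geo)


def save_image_tiff(path: str, image: Image2D) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32))


def load_image_tiff(path: str, pixel_size: float) -> Image2D:
    return Image2D(tifffile.imread(path).astype(np.float64), pixel_size)


def save_pairs(path: str, pairs) -> None:
    """Write a phantom-pair suite with its seed/spec manifest."""
    manifest = []
    with h5py.File(path, "w") as f:
        for i, pair in enumerate(pairs):
            g = f.create_group(f"pair{i:03d}")
            g.create_dataset("clean", data=pair.clean.values.astype(np.float32))
            g.create_dataset("corrupted", data=pair.corrupted.values.astype(np.float32))
            g.create_dataset("metal_mask", data=pair.metal_mask.astype(np.uint8))
            sds = g.create_dataset(
                "sino_corrupted", data=pair.corrupted_sino.values.astype(np.float32)
            )
            for key, val in pair.corrupted_sino.geometry.to_attrs().items():
                sds.attrs[key] = val
            g.attrs["pixel_size_mm"] = pair.clean.pixel_size
            manifest.append({"seed": pair.seed, "spec": asdict(pair.spec)})
        f.attrs["manifest"] = json.dumps(manifest)


def load_pairs(path: str):
    """Read a phantom-pair suite written by :func:`save_pairs`."""
    from .phantom import PhantomPair, PhantomSpec

    pairs = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        for i, meta in enumerate(manifest):
            g = f[f"pair{i:03d}"]
            ps = float(g.attrs["pixel_size_mm"])
            sds = g["sino_corrupted"]
            geo = FanBeamGeometry.from_attrs(dict(sds.attrs))
            pairs.append(
                PhantomPair(
                    clean=Image2D(g["clean"][()].astype(np.float64), ps),
                    corrupted=Image2D(g["corrupted"][()].astype(np.float64), ps),
                    corrupted_sino=Sinogram(sds[()].astype(np.float64), geo),
                    metal_mask=g["metal_mask"][()].astype(bool),
                    spec=PhantomSpec(**meta["spec"]),
                    seed=int(meta["seed"]),
                )
            )
    return pairs


# --------------------------------------------------------------------------
# model checkpoints
# --------------------------------------------------------------------------

def _param_arrays(module) -> list[np.ndarray]:
    return [p.value for p in module.params()]


def save_checkpoint(path: str, obj) -> None:
    """Serialize a VQCodec, LatentDiffusion or SegModel to one .npz archive."""
    from .codec import VQCodec
    from .diffusion import LatentDiffusion
    from .segmentation import SegModel

    arrays: dict[str, np.ndarray] = {}
    if isinstance(obj, VQCodec):
        header = {
            "kind": "vq_codec",
            "k": obj.codebook.k,
            "d": obj.codebook.d,
            "channels": [obj.e_in.w.value.shape[0], obj.e_d1.w.value.shape[0]],
            "window": list(obj.window),
            "trained": bool(obj.trained),
        }
        arrays["codebook"] = obj.codebook.vectors
        arrays["usage"] = obj.codebook.usage
        for i, a in enumerate(_param_arrays(obj)):
            arrays[f"p{i:04d}"] = a
    elif isinstance(obj, LatentDiffusion):
        c0 = obj.model.enc0.conv1.w.value.shape[0]
        c1 = obj.model.down1.w.value.shape[0]
        c2 = obj.model.down2.w.value.shape[0]
        header = {
            "kind": "latent_diffusion",
            "channels": [c0, c1, c2],
            "temb_dim": obj.model.temb_dim,
            "d": int(obj.latent_mean.shape[0]),
            "trained": bool(obj.trained),
        }
        arrays["betas"] = obj.sched.betas
        arrays["latent_mean"] = obj.latent_mean
        arrays["latent_std"] = obj.latent_std
        for i, a in enumerate(_param_arrays(obj.model)):
            arrays[f"p{i:04d}"] = a
        # the codec rides along in its own sub-archive fields
        arrays["codebook"] = obj.codec.codebook.vectors
        arrays["usage"] = obj.codec.codebook.usage
        for i, a in enumerate(_param_arrays(obj.codec)):
            arrays[f"c{i:04d}"] = a
        header["codec"] = {
            "k": obj.codec.codebook.k,
            "d": obj.codec.codebook.d,
            "channels": [obj.codec.e_in.w.value.shape[0], obj.codec.e_d1.w.value.shape[0]],
            "window": list(obj.codec.window),
            "trained": bool(obj.codec.trained),
        }
    elif isinstance(obj, SegModel):
        c0 = obj.net.enc0.conv1.w.value.shape[0]
        c1 = obj.net.down1.w.value.shape[0]
        c2 = obj.net.down2.w.value.shape[0]
        header = {
            "kind": "seg_model",
            "channels": [c0, c1, c2],
            "window": list(obj.window),
            "trained": bool(obj.trained),
        }
        for i, a in enumerate(_param_arrays(obj.net)):
            arrays[f"p{i:04d}"] = a
    else:
        raise TypeError(f"cannot checkpoint object of type {type(obj).__name__}")
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _restore_params(module, archive, prefix: str) -> None:
    for i, p in enumerate(module.params()):
        stored = archive[f"{prefix}{i:04d}"]
        if stored.shape != p.value.shape:
            raise ValueError("checkpoint/architecture mismatch")
        p.value[...] = stored


def load_checkpoint(path: str):
    """Rebuild the object saved by :func:`save_checkpoint`."""
    from .codec import Codebook, VQCodec
    from .diffusion import DiffusionSchedule, LatentDiffusion
    from .nn import UNet
    from .segmentation import SegModel

    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        kind = header["kind"]
        if kind == "vq_codec":
            codec = VQCodec(
                k=header["k"], d=header["d"], channels=tuple(header["channels"]),
                window=tuple(header["window"]),
            )
            _restore_params(codec, z, "p")
            codec.codebook = Codebook(z["codebook"].copy(), z["usage"].copy())
            codec.trained = header["trained"]
            return codec
        if kind == "seg_model":
            net = UNet(1, 1, tuple(header["channels"]))
            model = SegModel(net=net, window=tuple(header["window"]), trained=header["trained"])
            _restore_params(net, z, "p")
            return model
        if kind == "latent_diffusion":
            ch = header["codec"]
            codec = VQCodec(
                k=ch["k"], d=ch["d"], channels=tuple(ch["channels"]), window=tuple(ch["window"])
            )
            _restore_params(codec, z, "c")
            codec.codebook = Codebook(z["codebook"].copy(), z["usage"].copy())
            codec.trained = ch["trained"]
            d = header["d"]
            model = UNet(2 * d, d, tuple(header["channels"]), temb_dim=header["temb_dim"])
            _restore_params(model, z, "p")
            return LatentDiffusion(
                model=model,
                sched=DiffusionSchedule(z["betas"].copy()),
                codec=codec,
                latent_mean=z["latent_mean"].copy(),
                latent_std=z["latent_std"].copy(),
                trained=header["trained"],
            )
        raise ValueError(f"unknown checkpoint kind {kind!r}")
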
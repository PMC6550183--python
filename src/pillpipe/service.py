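"""Web service exposing the two pipeline stages, plus the offline pipeline.

``/detect`` locates pills: it runs the segmentation network (consumer-mode
post-processing) and responds with bounding-box / confidence pairs.  The
client crops the source image itself and posts each crop to ``/identify``,
which assumes a single, roughly centered pill and responds with the ranked
top-5 (NDC, confidence) list.  Images arrive as multipart/form-data file
fields or as JSON ``{"image": <base64>}``; both are accepted.

The app is plain WSGI (servable with ``wsgiref`` or any WSGI server).
"""

from __future__ import annotations

import base64
import io
import json
from email.parser import BytesParser
from email.policy import default as default_policy

import numpy as np
from PIL import Image, UnidentifiedImageError

from .classifier import Classifier, NDCLabelMap, predict_topk
from .localization import Detector, mask_to_detections, predict_mask
from .standardize import crop_pad_resize

MAX_BODY_BYTES = 20 * 1024 * 1024


# ------------------------------------------------------- offline pipeline --

def identify_pills(image: np.ndarray, detector: Detector, model: Classifier,
                   label_map: NDCLabelMap, k: int = 5, threshold: float = 0.5):
    """Full two-stage pipeline on one image.

    Returns a list of ``{"box", "score", "predictions"}`` dicts, one per
    detected pill, where predictions are the top-k (ndc, confidence) pairs.
    """
    prob = predict_mask(detector, image)
    detections = mask_to_detections(prob, threshold=threshold, consumer_mode=True)
    results = []
    for det in detections:
        crop = crop_pad_resize(image, det.box, out_size=model.spec.input_size)
        pred = predict_topk(model, crop.image, label_map, k=k)
        results.append({"box": list(det.box), "score": det.score,
                        "predictions": [{"ndc": n, "confidence": c}
                                        for n, c in pred]})
    return results


# ------------------------------------------------------------- WSGI plumbing --

class ClientError(Exception):
    def __init__(self, message, status="400 Bad Request"):
        super().__init__(message)
        self.status = status


def _decode_image(environ) -> np.ndarray:
    try:
        length = int(environ.get("CONTENT_LENGTH") or 0)
    except ValueError:
        raise ClientError("invalid Content-Length")
    if length > MAX_BODY_BYTES:
        raise ClientError("payload too large", "413 Request Entity Too Large")
    body = environ["wsgi.input"].read(length)
    ctype = environ.get("CONTENT_TYPE", "")
    raw = None
    if ctype.startswith("application/json"):
        try:
            payload = json.loads(body)
            raw = base64.b64decode(payload["image"], validate=True)
        except Exception:
            raise ClientError("expected JSON body {\"image\": <base64>}")
    elif ctype.startswith("multipart/form-data"):
        msg = BytesParser(policy=default_policy).parsebytes(
            b"Content-Type: " + ctype.encode() + b"\r\n\r\n" + body)
        for part in msg.iter_parts():
            if part.get_content_disposition() == "form-data":
                raw = part.get_payload(decode=True)
                break
        if raw is None:
            raise ClientError("no file field in multipart body")
    else:
        raw = body  # raw image bytes
    try:
        img = Image.open(io.BytesIO(raw)).convert("RGB")
    except (UnidentifiedImageError, OSError, ValueError):
        raise ClientError("payload is not a decodable image")
    return np.asarray(img)


def _json_response(start_response, status, obj):
    body = json.dumps(obj).encode()
    start_response(status, [("Content-Type", "application/json"),
                            ("Content-Length", str(len(body)))])
    return [body]


class PillService:
    """WSGI application wrapping a detector and a classifier."""

    def __init__(self, detector: Detector, model: Classifier,
                 label_map: NDCLabelMap, k: int = 5):
        self.detector = detector
        self.model = model
        self.label_map = label_map
        self.k = k

    # -- endpoint logic ----------------------------------------------------

    def detect(self, image: np.ndarray) -> dict:
        h, w, _ = self.detector.spec.input_shape
        ih, iw = image.shape[:2]
        if (ih, iw) != (h, w):
            resized = np.asarray(Image.fromarray(image).resize((w, h),
                                                               Image.BILINEAR))
        else:
            resized = image
        prob = predict_mask(self.detector, resized)
        dets = mask_to_detections(prob, consumer_mode=True)
        fr, fc = ih / h, iw / w
        out = []
        for d in dets:
            r0, c0, r1, c1 = d.box
            box = [int(np.floor(r0 * fr)), int(np.floor(c0 * fc)),
                   min(int(np.ceil(r1 * fr)), ih), min(int(np.ceil(c1 * fc)), iw)]
            out.append({"box": box, "score": d.score})
        return {"version": 1, "detections": out}

    def identify(self, image: np.ndarray) -> dict:
        size = self.model.spec.input_size
        if image.shape[:2] != (size, size):
            crop = crop_pad_resize(image, (0, 0, image.shape[0], image.shape[1]),
                                   out_size=size)
            image = crop.image
        pred = predict_topk(self.model, image, self.label_map, k=self.k)
        return {"version": 1,
                "predictions": [{"ndc": n, "confidence": c} for n, c in pred]}

    # -- WSGI --------------------------------------------------------------

    def __call__(self, environ, start_response):
        path = environ.get("PATH_INFO", "")
        method = environ.get("REQUEST_METHOD", "GET")
        if path not in ("/detect", "/identify"):
            return _json_response(start_response, "404 Not Found",
                                  {"error": f"unknown path {path}"})
        if method != "POST":
            return _json_response(start_response, "405 Method Not Allowed",
                                  {"error": "POST an image"})
        try:
            image = _decode_image(environ)
            result = self.detect(image) if path == "/detect" else self.identify(image)
        except ClientError as exc:
            return _json_response(start_response, exc.status, {"error": str(exc)})
        return _json_response(start_response, "200 OK", result)


def serve(app: PillService, host: str = "127.0.0.1", port: int = 8080):
    from wsgiref.simple_server import make_server
    with make_server(host, port, app) as httpd:
        print(f"pillpipe service on http://{host}:{port} (/detect, /identify)")
        httpd.serve_forever()
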
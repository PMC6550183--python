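"""Convolutional feature extractors.

Builders return ``(Sequential, feature_width)`` where the sequential ends in
global average pooling, i.e. its output is ``(N, feature_width)``.  The four
ImageNet architectures follow their published layer configurations so that
total parameter counts (including batch-norm statistics) match the reference
implementations; they run inference but are not trainable here.  The
``small_test`` backbone is a fully trainable CNN with the same contract, sized
for CPU experiments.
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2D, BatchNorm, Conv2D, DepthwiseConv2D, Dense,
                     GlobalAvgPool, MaxPool2D, ReLU, Sigmoid, UpSample2D)
from .model import Parallel, Residual, Sequential


def _conv_bn_relu(c_in, c_out, k, stride=1, padding="same", use_bias=False,
                  bn_scale=True, rng=None, name="cbr"):
    return [Conv2D(c_in, c_out, k, stride=stride, padding=padding,
                   use_bias=use_bias, rng=rng, name=name),
            BatchNorm(c_out, scale=bn_scale, name=name + ".bn"),
            ReLU()]


# ---------------------------------------------------------------- ResNet50 --

def _bottleneck(c_in, f, c_out, stride, project, rng):
    main = Sequential(
        _conv_bn_relu(c_in, f, 1, stride=stride, rng=rng, use_bias=True)[:-1] + [ReLU()]
        + _conv_bn_relu(f, f, 3, rng=rng, use_bias=True)[:-1] + [ReLU()]
        + [Conv2D(f, c_out, 1, rng=rng, use_bias=True), BatchNorm(c_out)])
    shortcut = None
    if project:
        shortcut = Sequential([Conv2D(c_in, c_out, 1, stride=stride, rng=rng,
                                      use_bias=True), BatchNorm(c_out)])
    return Residual(main, shortcut)


def resnet50(rng=None):
    """ResNet-50 trunk up to (and including) the final global average pooling."""
    rng = rng or np.random.default_rng(0)
    layers = [Conv2D(3, 64, 7, stride=2, padding=3, use_bias=True, rng=rng,
                     name="conv1"),
              BatchNorm(64), ReLU(),
              MaxPool2D(3, stride=2, padding="same")]
    cfg = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
    c_in = 64
    for f, c_out, n_blocks, stride in cfg:
        for b in range(n_blocks):
            layers.append(_bottleneck(c_in, f, c_out,
                                      stride if b == 0 else 1, b == 0, rng))
            c_in = c_out
    layers.append(GlobalAvgPool())
    return Sequential(layers, name="resnet50"), 2048


# --------------------------------------------------------------- MobileNet --

def _dw_separable(c_in, c_out, stride, rng):
    return [DepthwiseConv2D(c_in, 3, stride=stride, rng=rng),
            BatchNorm(c_in), ReLU(),
            Conv2D(c_in, c_out, 1, use_bias=False, rng=rng),
            BatchNorm(c_out), ReLU()]


def mobilenet(rng=None):
    """MobileNet v1 (width 1.0) trunk with final global average pooling."""
    rng = rng or np.random.default_rng(0)
    layers = _conv_bn_relu(3, 32, 3, stride=2, rng=rng)
    cfg = [(32, 64, 1), (64, 128, 2), (128, 128, 1), (128, 256, 2),
           (256, 256, 1), (256, 512, 2), (512, 512, 1), (512, 512, 1),
           (512, 512, 1), (512, 512, 1), (512, 512, 1), (512, 1024, 2),
           (1024, 1024, 1)]
    for c_in, c_out, stride in cfg:
        layers += _dw_separable(c_in, c_out, stride, rng)
    layers.append(GlobalAvgPool())
    return Sequential(layers, name="mobilenet"), 1024


# -------------------------------------------------------- SqueezeNet v1.1 --

def _fire(c_in, squeeze, expand, rng):
    sq = Sequential([Conv2D(c_in, squeeze, 1, use_bias=True, rng=rng), ReLU()])
    e1 = Sequential([Conv2D(squeeze, expand, 1, use_bias=True, rng=rng), ReLU()])
    e3 = Sequential([Conv2D(squeeze, expand, 3, use_bias=True, rng=rng), ReLU()])
    return Sequential([sq, Parallel([e1, e3])])


def squeezenet(rng=None):
    """SqueezeNet v1.1 trunk (conv1 3x3/2) with global average pooling."""
    rng = rng or np.random.default_rng(0)
    layers = [Conv2D(3, 64, 3, stride=2, padding="valid", use_bias=True, rng=rng),
              ReLU(), MaxPool2D(3, stride=2, padding="valid"),
              _fire(64, 16, 64, rng), _fire(128, 16, 64, rng),
              MaxPool2D(3, stride=2, padding="valid"),
              _fire(128, 32, 128, rng), _fire(256, 32, 128, rng),
              MaxPool2D(3, stride=2, padding="valid"),
              _fire(256, 48, 192, rng), _fire(384, 48, 192, rng),
              _fire(384, 64, 256, rng), _fire(512, 64, 256, rng),
              GlobalAvgPool()]
    return Sequential(layers, name="squeezenet"), 512


# ------------------------------------------------------------ InceptionV3 --

def _cb(c_in, c_out, k, stride=1, padding="same", rng=None):
    """Inception conv unit: conv (no bias) + BN without gamma + relu."""
    return Sequential(_conv_bn_relu(c_in, c_out, k, stride=stride, padding=padding,
                                    bn_scale=False, rng=rng))


def _inception_a(c_in, pool_proj, rng):
    return Parallel([
        _cb(c_in, 64, 1, rng=rng),
        Sequential([_cb(c_in, 48, 1, rng=rng), _cb(48, 64, 5, rng=rng)]),
        Sequential([_cb(c_in, 64, 1, rng=rng), _cb(64, 96, 3, rng=rng),
                    _cb(96, 96, 3, rng=rng)]),
        Sequential([AvgPool2D(3, 1, "same"), _cb(c_in, pool_proj, 1, rng=rng)]),
    ])


def _inception_b(c_in, mid, rng):
    return Parallel([
        _cb(c_in, 192, 1, rng=rng),
        Sequential([_cb(c_in, mid, 1, rng=rng), _cb(mid, mid, (1, 7), rng=rng),
                    _cb(mid, 192, (7, 1), rng=rng)]),
        Sequential([_cb(c_in, mid, 1, rng=rng), _cb(mid, mid, (7, 1), rng=rng),
                    _cb(mid, mid, (1, 7), rng=rng), _cb(mid, mid, (7, 1), rng=rng),
                    _cb(mid, 192, (1, 7), rng=rng)]),
        Sequential([AvgPool2D(3, 1, "same"), _cb(c_in, 192, 1, rng=rng)]),
    ])


def _inception_c(c_in, rng):
    split33 = Parallel([_cb(384, 384, (1, 3), rng=rng), _cb(384, 384, (3, 1), rng=rng)])
    split33b = Parallel([_cb(384, 384, (1, 3), rng=rng), _cb(384, 384, (3, 1), rng=rng)])
    return Parallel([
        _cb(c_in, 320, 1, rng=rng),
        Sequential([_cb(c_in, 384, 1, rng=rng), split33]),
        Sequential([_cb(c_in, 448, 1, rng=rng), _cb(448, 384, 3, rng=rng), split33b]),
        Sequential([AvgPool2D(3, 1, "same"), _cb(c_in, 192, 1, rng=rng)]),
    ])


def inception_v3(rng=None):
    """InceptionV3 trunk with global average pooling (input-size flexible)."""
    rng = rng or np.random.default_rng(0)
    layers = [
        _cb(3, 32, 3, stride=2, padding="valid", rng=rng),
        _cb(32, 32, 3, padding="valid", rng=rng),
        _cb(32, 64, 3, rng=rng),
        MaxPool2D(3, stride=2, padding="valid"),
        _cb(64, 80, 1, padding="valid", rng=rng),
        _cb(80, 192, 3, padding="valid", rng=rng),
        MaxPool2D(3, stride=2, padding="valid"),
        _inception_a(192, 32, rng), _inception_a(256, 64, rng),
        _inception_a(288, 64, rng),
        # reduction to 768 channels
        Parallel([
            _cb(288, 384, 3, stride=2, padding="valid", rng=rng),
            Sequential([_cb(288, 64, 1, rng=rng), _cb(64, 96, 3, rng=rng),
                        _cb(96, 96, 3, stride=2, padding="valid", rng=rng)]),
            Sequential([MaxPool2D(3, stride=2, padding="valid")]),
        ]),
        _inception_b(768, 128, rng), _inception_b(768, 160, rng),
        _inception_b(768, 160, rng), _inception_b(768, 192, rng),
        # reduction to 1280 channels
        Parallel([
            Sequential([_cb(768, 192, 1, rng=rng),
                        _cb(192, 320, 3, stride=2, padding="valid", rng=rng)]),
            Sequential([_cb(768, 192, 1, rng=rng), _cb(192, 192, (1, 7), rng=rng),
                        _cb(192, 192, (7, 1), rng=rng),
                        _cb(192, 192, 3, stride=2, padding="valid", rng=rng)]),
            Sequential([MaxPool2D(3, stride=2, padding="valid")]),
        ]),
        _inception_c(1280, rng), _inception_c(2048, rng),
        GlobalAvgPool(),
    ]
    return Sequential(layers, name="inception_v3"), 2048


# -------------------------------------------------------------- small test --

def small_test(rng=None, width=12):
    """Small trainable CNN backbone for CPU-scale experiments (224x224 input).

    Downsamples aggressively up front (stride-4 stem, 4x pool) so a full
    fine-tuning run stays tractable on one CPU core; the deeper layers widen
    to 8x the stem width, which costs little at 7x7 resolution but gives the
    pooled feature enough capacity to separate look-alike classes.
    """
    rng = rng or np.random.default_rng(0)
    w = width
    layers = (_conv_bn_relu(3, w, 5, stride=4, rng=rng)
              + [MaxPool2D(4)]
              + _conv_bn_relu(w, 3 * w, 3, rng=rng)
              + [MaxPool2D(2)]
              + _conv_bn_relu(3 * w, 8 * w, 3, rng=rng)
              + [GlobalAvgPool()])
    return Sequential(layers, name="small_test"), 8 * w


BACKBONES = {
    "RESNET50": resnet50,
    "MOBILENET": mobilenet,
    "SQUEEZENET": squeezenet,
    "INCEPTIONV3": inception_v3,
    "SMALL_TEST": small_test,
}


# ------------------------------------------------------------- detectors --

def small_fcn(rng=None, width=12):
    """4-level encoder-decoder FCN producing a sigmoid mask at input size.

    Fully trainable; overall stride 4 (two 2x2 pools mirrored by two nearest
    upsamplings).  Contains no dense layers.
    """
    rng = rng or np.random.default_rng(0)
    w = width
    layers = (_conv_bn_relu(3, w, 3, rng=rng)
              + [MaxPool2D(2)]
              + _conv_bn_relu(w, 2 * w, 3, rng=rng)
              + [MaxPool2D(2)]
              + _conv_bn_relu(2 * w, 4 * w, 3, rng=rng)
              + _conv_bn_relu(4 * w, 4 * w, 3, rng=rng)
              + [UpSample2D(2)]
              + _conv_bn_relu(4 * w, 2 * w, 3, rng=rng)
              + [UpSample2D(2)]
              + _conv_bn_relu(2 * w, w, 3, rng=rng)
              + [Conv2D(w, 1, 1, use_bias=True, rng=rng, name="score"),
                 Sigmoid()])
    return Sequential(layers, name="small_fcn"), 4


class FCNVGG16(Sequential):
    """FCN-8s-style segmentation head on a VGG16 encoder (sigmoid output).

    The two classifier convolutions (7x7/4096 and 1x1/4096) replace VGG's
    fully connected layers, so the network is fully convolutional; skip
    connections from pool3 and pool4 refine the 32x-stride score map, and
    nearest-neighbour upsampling restores input resolution.  Inference and
    parameter counting only (use ``small_fcn`` for CPU training).
    """

    def __init__(self, rng=None):
        rng = rng or np.random.default_rng(0)

        def block(c_in, c_out, n):
            ls = []
            for i in range(n):
                ls += [Conv2D(c_in if i == 0 else c_out, c_out, 3, rng=rng),
                       ReLU()]
            ls.append(MaxPool2D(2))
            return Sequential(ls)

        self.block1 = block(3, 64, 2)
        self.block2 = block(64, 128, 2)
        self.block3 = block(128, 256, 3)
        self.block4 = block(256, 512, 3)
        self.block5 = block(512, 512, 3)
        self.fc6 = Sequential([Conv2D(512, 4096, 7, rng=rng), ReLU()])
        self.fc7 = Sequential([Conv2D(4096, 4096, 1, rng=rng), ReLU()])
        self.score32 = Conv2D(4096, 1, 1, rng=rng, name="score32")
        self.score_pool4 = Conv2D(512, 1, 1, rng=rng, name="score_pool4")
        self.score_pool3 = Conv2D(256, 1, 1, rng=rng, name="score_pool3")
        self.up2a = UpSample2D(2)
        self.up2b = UpSample2D(2)
        self.up8 = UpSample2D(8)
        self.sigmoid = Sigmoid()
        super().__init__(
            [self.block1, self.block2, self.block3, self.block4, self.block5,
             self.fc6, self.fc7, self.score32, self.score_pool4,
             self.score_pool3, self.up2a, self.up2b, self.up8, self.sigmoid],
            name="fcn_vgg16")

    def forward(self, x, training=False):
        p1 = self.block1.forward(x)
        p2 = self.block2.forward(p1)
        p3 = self.block3.forward(p2)
        p4 = self.block4.forward(p3)
        p5 = self.block5.forward(p4)
        s32 = self.score32.forward(self.fc7.forward(self.fc6.forward(p5)))
        s16 = self.up2a.forward(s32) + self.score_pool4.forward(p4)
        s8 = self.up2b.forward(s16) + self.score_pool3.forward(p3)
        return self.sigmoid.forward(self.up8.forward(s8))

    def backward(self, grad):
        raise NotImplementedError("FCNVGG16 is inference-only; train small_fcn")
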
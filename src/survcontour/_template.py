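"""Self-contained HTML templates for the interactive figures.

Everything is inlined -- data as a JSON block, rendering and hover logic as
plain canvas JavaScript -- so the exported file works offline with no
network fetches.  The token ``__PAYLOAD__`` is replaced with the figure's
JSON payload at export time.
"""

PAGE = """<!doctype html>
<html>
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
  body { font-family: system-ui, sans-serif; margin: 16px; background: #fff; }
  #wrap { position: relative; display: inline-block; }
  #hover { position: absolute; pointer-events: none; background: rgba(255,255,255,0.92);
           border: 1px solid #888; border-radius: 4px; padding: 3px 7px;
           font-size: 13px; display: none; white-space: nowrap; }
  canvas { display: block; }
  .note { color: #555; font-size: 12px; margin-top: 6px; }
</style>
</head>
<body>
<div id="wrap">
  <canvas id="plot" width="960" height="560"></canvas>
  <div id="hover"></div>
</div>
<div class="note" id="note"></div>
<script type="application/json" id="survcontour-data">__PAYLOAD__</script>
<script>
"use strict";
const payload = JSON.parse(document.getElementById("survcontour-data").textContent);
__SCRIPT__
</script>
</body>
</html>
"""

CONTOUR_SCRIPT = """
const S = payload.surface, opt = payload.options, colors = payload.colors;
const times = S.times, cov = S.covariate, V = S.values;
const hist = payload.histogram;
const cvs = document.getElementById("plot"), ctx = cvs.getContext("2d");
const ml = 70, mt = 20, mb = 70, histW = hist ? 150 : 0, gap = hist ? 40 : 0, mr = 15;
const plotW = cvs.width - ml - mr - histW - gap, plotH = cvs.height - mt - mb;
const tmax = times[times.length - 1], x0 = cov[0], x1 = cov[cov.length - 1];
const tx = t => ml + (t / tmax) * plotW;
const ty = x => mt + plotH - ((x - x0) / (x1 - x0)) * plotH;

function bandColor(v) {
  const k = Math.min(Math.floor(v / opt.level_step), colors.band_colors.length - 1);
  return colors.band_colors[Math.max(k, 0)];
}
// value lookup: step in time (last knot <= t), linear in the covariate
function lastKnot(t) {
  let lo = 0, hi = times.length - 1;
  while (lo < hi) { const mid = (lo + hi + 1) >> 1; if (times[mid] <= t) lo = mid; else hi = mid - 1; }
  return lo;
}
function valueAt(t, x) {
  const j = lastKnot(t);
  let i = 0;
  while (i < cov.length - 2 && cov[i + 1] < x) i++;
  const w = cov[i + 1] === cov[i] ? 0 : (x - cov[i]) / (cov[i + 1] - cov[i]);
  return V[i][j] * (1 - w) + V[i + 1][j] * Math.min(Math.max(w, 0), 1);
}

function draw() {
  ctx.clearRect(0, 0, cvs.width, cvs.height);
  for (let i = 0; i < cov.length; i++) {
    const ylo = i === 0 ? cov[0] : 0.5 * (cov[i - 1] + cov[i]);
    const yhi = i === cov.length - 1 ? cov[cov.length - 1] : 0.5 * (cov[i] + cov[i + 1]);
    for (let j = 0; j + 1 < times.length; j++) {
      ctx.fillStyle = bandColor(V[i][j]);
      ctx.fillRect(tx(times[j]), ty(yhi), tx(times[j + 1]) - tx(times[j]) + 0.5, ty(ylo) - ty(yhi) + 0.5);
    }
  }
  ctx.strokeStyle = "#333"; ctx.strokeRect(ml, mt, plotW, plotH);
  ctx.fillStyle = "#000"; ctx.font = "12px sans-serif";
  ctx.textAlign = "center";
  for (let k = 0; k <= 5; k++) {
    const t = tmax * k / 5;
    ctx.fillText(t.toPrecision(3), tx(t), mt + plotH + 16);
  }
  ctx.fillText(opt.time_label, ml + plotW / 2, mt + plotH + 34);
  ctx.save(); ctx.textAlign = "right";
  for (let k = 0; k <= 5; k++) {
    const x = x0 + (x1 - x0) * k / 5;
    ctx.fillText(x.toPrecision(3), ml - 6, ty(x) + 4);
  }
  ctx.restore();
  ctx.save();
  ctx.translate(16, mt + plotH / 2); ctx.rotate(-Math.PI / 2);
  ctx.textAlign = "center"; ctx.fillText(opt.predictor_label, 0, 0);
  ctx.restore();
  // colorbar
  const cbY = mt + plotH + 44, cbW = plotW, nb = colors.band_colors.length;
  for (let k = 0; k < nb; k++) {
    ctx.fillStyle = colors.band_colors[k];
    ctx.fillRect(ml + cbW * k / nb, cbY, cbW / nb + 0.5, 10);
  }
  ctx.strokeRect(ml, cbY, cbW, 10);
  ctx.fillStyle = "#000"; ctx.textAlign = "center";
  for (let k = 0; k <= 5; k++) ctx.fillText((k * 20) + "%", ml + cbW * k / 5, cbY + 22);
  // histogram of the predictor, shared y-axis
  if (hist) {
    const hx = ml + plotW + gap;
    const cmax = Math.max(...hist.map(b => b[2]));
    ctx.fillStyle = opt.hist_color;
    for (const [l, r, c] of hist) {
      const y1 = ty(Math.min(Math.max(l, x0), x1)), y2 = ty(Math.min(Math.max(r, x0), x1));
      ctx.fillRect(hx, Math.min(y1, y2), (c / cmax) * histW, Math.abs(y1 - y2) || 2);
    }
    ctx.strokeStyle = "#333";
    ctx.beginPath(); ctx.moveTo(hx, mt); ctx.lineTo(hx, mt + plotH); ctx.stroke();
    ctx.fillStyle = "#000";
    ctx.fillText("count", hx + histW / 2, mt + plotH + 16);
  }
}
draw();

const box = document.getElementById("hover");
const label = S.outcome_type === "survival" ? "survival" : "cumulative incidence";
cvs.addEventListener("mousemove", ev => {
  const rect = cvs.getBoundingClientRect();
  const px = ev.clientX - rect.left, py = ev.clientY - rect.top;
  const t = (px - ml) / plotW * tmax;
  const x = x0 + (mt + plotH - py) / plotH * (x1 - x0);
  if (t < 0 || t > tmax || x < x0 || x > x1) { box.style.display = "none"; return; }
  const v = valueAt(t, x);
  box.style.display = "block";
  box.style.left = (px + 14) + "px"; box.style.top = (py + 14) + "px";
  box.textContent = opt.time_label + " = " + t.toPrecision(4) + ", " +
    opt.predictor_label + " = " + x.toPrecision(4) + ": " + label + " = " +
    (100 * v).toFixed(opt.percent_decimals) + "%";
});
cvs.addEventListener("mouseleave", () => { box.style.display = "none"; });
document.getElementById("note").textContent =
  "Hover to read predicted " + label + "; darker colors = worse outcome.";
"""

SURFACE3D_SCRIPT = """
const S = payload.surface, opt = payload.options, colors = payload.colors;
const layers = payload.layers;  // drawn in order; each {z, opacity}
const times = S.times, cov = S.covariate;
const cvs = document.getElementById("plot"), ctx = cvs.getContext("2d");
const tmax = times[times.length - 1], x0 = cov[0], x1 = cov[cov.length - 1];
let yaw = -0.65, pitch = 0.42;
const cx = cvs.width / 2, cy = cvs.height / 2, scale = Math.min(cvs.width, cvs.height) * 0.62;

function project(u, v, w) {  // unit-cube coords -> screen + depth
  const X = u - 0.5, Y = v - 0.5, Z = w - 0.5;
  const x1r = X * Math.cos(yaw) + Y * Math.sin(yaw);
  const y1r = -X * Math.sin(yaw) + Y * Math.cos(yaw);
  const z2 = Z * Math.cos(pitch) - y1r * Math.sin(pitch);
  const depth = y1r * Math.cos(pitch) + Z * Math.sin(pitch);
  return [cx + x1r * scale, cy - z2 * scale * 0.9, depth];
}
function cellColor(v, opacity) {
  const k = Math.min(Math.floor(v / opt.level_step), colors.band_colors.length - 1);
  const hex = colors.band_colors[Math.max(k, 0)];
  const r = parseInt(hex.slice(1, 3), 16), g = parseInt(hex.slice(3, 5), 16),
        b = parseInt(hex.slice(5, 7), 16);
  return "rgba(" + r + "," + g + "," + b + "," + opacity + ")";
}
function draw() {
  ctx.clearRect(0, 0, cvs.width, cvs.height);
  const quads = [];
  for (const layer of layers) {
    const Z = layer.z;
    for (let i = 0; i + 1 < cov.length; i++) {
      for (let j = 0; j + 1 < times.length; j++) {
        const pts = [[i, j], [i, j + 1], [i + 1, j + 1], [i + 1, j]].map(([a, b]) =>
          project(times[b] / tmax, (cov[a] - x0) / (x1 - x0), Z[a][b]));
        const depth = (pts[0][2] + pts[1][2] + pts[2][2] + pts[3][2]) / 4;
        const v = (Z[i][j] + Z[i][j + 1] + Z[i + 1][j] + Z[i + 1][j + 1]) / 4;
        quads.push({ pts, depth, fill: cellColor(v, layer.opacity) });
      }
    }
  }
  quads.sort((a, b) => a.depth - b.depth);
  for (const q of quads) {
    ctx.beginPath();
    ctx.moveTo(q.pts[0][0], q.pts[0][1]);
    for (let k = 1; k < 4; k++) ctx.lineTo(q.pts[k][0], q.pts[k][1]);
    ctx.closePath();
    ctx.fillStyle = q.fill; ctx.fill();
  }
  ctx.fillStyle = "#000"; ctx.font = "13px sans-serif"; ctx.textAlign = "center";
  const o = project(0.5, -0.08, 0); ctx.fillText(opt.time_label, o[0], o[1]);
  const o2 = project(-0.1, 0.5, 0); ctx.fillText(opt.predictor_label, o2[0], o2[1]);
}
draw();
let dragging = false, lastX = 0, lastY = 0;
cvs.addEventListener("mousedown", ev => { dragging = true; lastX = ev.clientX; lastY = ev.clientY; });
window.addEventListener("mouseup", () => { dragging = false; });
window.addEventListener("mousemove", ev => {
  if (!dragging) return;
  yaw += (ev.clientX - lastX) * 0.01;
  pitch = Math.min(1.4, Math.max(-1.4, pitch + (ev.clientY - lastY) * 0.01));
  lastX = ev.clientX; lastY = ev.clientY;
  draw();
});
document.getElementById("note").textContent =
  "Drag to rotate. " + (layers.length === 3 ?
  "Semitransparent layers show the " + Math.round(100 * (S.ci_level || 0.95)) + "% confidence band." : "");
"""


def render_page(kind: str, payload_json: str, title: str) -> str:
    script = CONTOUR_SCRIPT if kind == "contour2d" else SURFACE3D_SCRIPT
    return (
        PAGE.replace("__TITLE__", title)
        .replace("__PAYLOAD__", payload_json)
        .replace("__SCRIPT__", script)
    )
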
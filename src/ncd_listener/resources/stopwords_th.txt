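# Thai stopword list (one token per line). Particles and function words only;
# disease/symptom matching for Thai runs on the raw text, so this list only
# affects word-frequency counts.
ครับ
ค่ะ
คะ
นะ
ก็
ที่
และ
แล้ว
จะ
ของ
ใน
ให้
ว่า
กับ
คือ
ได้
ไป
มา
ไม่
ด้วย
อยู่
มาก
เลย
อีก
ยัง
ต้อง
เมื่อ
จาก
โดย
ซึ่ง
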
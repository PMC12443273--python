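# Dictionary for longest-match Thai word segmentation (one word per line).
# Curated around the NCD domain: disease names, symptoms, treatments,
# behaviours, kinship/pronoun cues, question particles and high-frequency
# function words. Extend freely; longer entries win over shorter prefixes.
มะเร็ง
มะเร็งปอด
มะเร็งเต้านม
เบาหวาน
โรคหัวใจ
โรคไต
โรคปอด
โรคหลอดเลือดสมอง
ความดัน
ความดันโลหิตสูง
หอบหืด
ถุงลมโป่งพอง
โรค
หัวใจ
ปอด
ไต
เหนื่อย
เหนื่อยง่าย
ไอเรื้อรัง
ไอ
เจ็บ
เจ็บหน้าอก
ปวด
ปวดหัว
เวียนหัว
อ่อนเพลีย
น้ำหนักลด
ชา
บวม
เหงื่อออก
หายใจ
หายใจลำบาก
คีโม
เคมีบำบัด
ฉายแสง
ผ่าตัด
ยา
กินยา
รักษา
หมอ
แพทย์
โรงพยาบาล
อินซูลิน
ฟอกไต
สูบบุหรี่
บุหรี่
เหล้า
ดื่มเหล้า
ออกกำลังกาย
อาหาร
ของหวาน
น้ำตาล
อ้วน
ความเครียด
นอนดึก
ผม
ฉัน
ดิฉัน
เขา
เธอ
คุณ
แม่
พ่อ
ยาย
ตา
ย่า
ปู่
พี่
น้อง
ลุง
ป้า
เพื่อน
ตัวเอง
ครอบครัว
ผู้ชาย
ผู้หญิง
ไหม
มั้ย
หรือเปล่า
ทำไม
อะไร
อย่างไร
ยังไง
ที่ไหน
เมื่อไหร่
เหรอ
หรอ
กี่
ใคร
เป็น
ไม่
ได้
มี
ไป
มา
ที่
และ
แล้ว
ก็
จะ
ของ
ใน
ให้
ว่า
กับ
คน
ปี
วัน
เดือน
เมื่อ
ต้อง
อยาก
รู้
รู้สึก
ดีขึ้น
หาย
เสียชีวิต
กำลังใจ
สู้
สู้ๆ
ขอบคุณ
ดูแล
สุขภาพ
ตรวจ
พบ
อาการ
เริ่ม
หลังจาก
ตอนนี้
มาก
ดี
ค่ะ
คะ
ครับ
นะ
ด้วย
ช่วย
บอก
เล่า
เคย
ทุกคน
ตั้งแต่
ระยะ
สุดท้าย
น้ำ
กิน
นอน
ทำงาน
บ้าน
เดิน
วิ่ง
ลด
เพิ่ม
ขึ้น
ลง
หนึ่ง
สอง
สาม
สี่
ตอนแรก
อยู่
เลย
อีก
ยัง
จาก
โดย
ซึ่ง
แชร์
โพสต์
ข้อมูล
ประสบการณ์
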
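terminology_id,problem_domain,category_label,preferred_label,synonym_labels,definition_text,cdrh_ncit_labels
T2A,device,電気的不良,ヒューズ切れ,,,
T2A,device,機器不良,アラーム異常,,,
T2A,device,不明,不明,,,
T2A,device,故障,バッテリ不良,,,
T2A,device,動作不良,バッテリ不良,,,
T2A,device,誤穿刺,誤穿刺,,,
T2A,patient,アレルギー症状,かゆみ,,,
T2A,patient,機能性障害,呼吸不全,,,
T2A,patient,炎症,痛み,,,
T2A,patient,炎症症状,皮膚炎,,,
T2A,patient,損傷,外傷,,,
T2B,device,ヒューズ切れ,ヒューズ溶断,,,
T2B,device,アラーム異常,異常検知不可,,,
T2B,device,不明,原因不明,,,
T2B,device,バッテリ不良,早期放電,,,
T2B,device,バッテリ不良,バッテリ駆動不良,,,
T2B,device,誤穿刺,誤穿刺,,,
T2B,patient,かゆみ,そう痒感,,,
T2B,patient,呼吸不全,動脈血酸素飽和度低下,,,
T2B,patient,痛み,のどの痛み,,,
T2B,patient,皮膚炎,痒み,,,
T2B,patient,外傷,損傷,,,
T3A,device,T3C-01a,剥離,はがれ,,
T3A,device,故障,変形,へこみ,,
T3A,device,故障,変形,折れ,,
T3A,device,故障,変形,曲がり,,
T3A,device,T3C-05a,誤作動,誤動作,,
T3A,device,T3C-06a,挿入不能,迷入,,
T3A,patient,T3C-07a,意図しない組織損傷,裂傷,,
T3A,patient,T3C-08a,残留,遺残,,
T3A,patient,T3C-09a,感染症,感染,,
T3A,patient,T3C-10a,感染症,感染,,
T3B,device,T3C-01b,はがれ,剥離,,
T3B,device,T3C-02b,へこみ,陥没,,
T3B,device,T3C-03b,折れ,折損,,
T3B,device,T3C-04b,曲がり,湾曲,,
T3B,device,T3C-05b,誤動作,意図しない動作,,
T3B,device,T3C-06b,迷入,網膜下迷入,,
T3B,patient,T3C-07b,裂傷,切り傷,,
T3B,patient,T3C-08b,遺残,異物残存,,
T3B,patient,T3C-09b,感染,患者感染,,
T3B,patient,T3C-10b,感染,合併症,,
T4A,device,アーチファクト,アーチファクト,,,
T4A,device,充電不良,バッテリ不良,,,
T4A,device,故障,バッテリ不良,,,
T4A,device,経時変化,劣化,,,
T4A,device,破損,劣化,,,
T4A,device,故障,変形,,,
T4A,device,成形不良,変形,,,
T4A,device,コンタクトレンズ不良,変形,,,
T4A,device,機械的不良,変形,,,
T4A,device,損傷,変形,,,
T4A,device,品質不良,変形,,,
T4A,patient,炎症症状,かぶれ,,,
T4A,patient,皮膚炎,かぶれ,,,
T4A,patient,骨折,骨折,,,
T4A,patient,損傷,骨折,,,
T4A,patient,組織障害,骨折,,,
T4A,patient,組織損傷,神経障害,,,
T4A,patient,視機能障害,失明,,,
T4A,patient,失明,失明,,,
T4A,patient,感染,アレルギー反応,,,
T4A,patient,ショック,アレルギー反応,,,
T4A,patient,眼疾患,アレルギー反応,,,
T4A,patient,アレルギー反応,アレルギー反応,,,
T4B,device,異常画像,アーチファクト,,,
T4B,device,動作不良,バッテリ不良,,,
T4B,device,故障,劣化,,,
T4B,device,不良,劣化,,,
T4B,device,破損,変形,,,
T4B,device,変形不良,変形,,,
T4B,device,分注ノズル折損・変形,変形,,,
T4B,device,不良,変形,,,
T4B,device,意図しない効果,変形,,,
T4B,patient,炎症,かぶれ,,,
T4B,patient,かぶれ,かぶれ,,,
T4B,patient,外傷,骨折,,,
T4B,patient,組織損傷,骨折,,,
T4B,patient,機能性障害,神経障害,,,
T4B,patient,視力障害,失明,,,
T4B,patient,炎症,アレルギー反応,,,
T4B,patient,アレルギー症状,アレルギー反応,,,
T4B,patient,損傷,アレルギー反応,,,
T5A,device,異常画像,アーチファクト,,信号処理などで、観測や解析の段階で発生したデータのエラーや信号のゆがみが画像に混入すること。,
T5A,device,電気的不良,ヒューズ切れ,,ヒューズが切断すること。,
T5A,device,故障,バッテリ不良,,バッテリ電圧・容量の低下,
T5A,device,故障,バッテリ不良,,バッテリ自体の不良,
T5A,device,T5CD-04,緩み,,ネジ、ロック等が緩むこと。,
T5A,device,T5CD-04,緩み,,ネジ等が緩み、当該部位の物理的な保持・作用に支障をきたす状態の事,
T5A,device,T5CD-04,緩み,,接続不良となる接続部のがたつき。,
T5A,device,T5CD-04,緩み,,装置又は器具の部分の固定が不良となること。,
T5A,patient,T5CP-01,感染症,,ポケット部位から感染症となる。,
T5A,patient,T5CP-02,心室細動,,心室が整合的な収縮を行なわず、各部の筋肉が無秩序に収縮する状態,
T5A,patient,T5CP-02,心室細動,,心室が規則に震えるように痙攣 (けいれん) する状態のこと。,
T5A,patient,T5CP-02,心室細動,,悪性の心室不整脈で、心室筋の持続的、非協調的な収縮によって特徴づけられ、心臓からの血流は途絶する。,
T5A,patient,T5CP-03,手術時間の延長,,医療機器の不具合により当初予定していたよりも手術時間が長引いてしまうこと。,
T5A,patient,T5CP-04,虹彩脱出,,眼球の穿孔部からの虹彩の一部が眼球外に脱出した状態。強角膜の穿孔性外傷や切開手術、または角膜軟化症・角膜炎が進行して角膜が穿孔したときに生じる。感染防止が重要で、速やかな虹彩整復手術を要する。,
T5A,patient,T5CP-04,虹彩脱出,,虹彩が脱出すること。,
T5A,patient,T5CP-05,感染,,病原微生物が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと,
T5A,patient,T5CP-05,感染,,微生物が、体内に侵入・定着した状態。,
T5A,patient,T5CP-05,感染,,病原微生物または感染性物質が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと,
T5A,patient,T5CP-05,感染,,微生物が人体に侵入、増殖、何らの症状が出現する症例。,
T5B,device,異常画像,アーチファクト,,目的としない信号が表示されること,
T5B,device,電気的不良,ヒューズ切れ,,過電流等によりヒューズが切れること,
T5B,device,故障,バッテリ不良,,バッテリの不良,
T5B,device,故障,バッテリ不良,,バッテリの異常でバッテリによる駆動ができないこと。,
T5B,device,T5CD-04,緩み,,ねじなどの締め付けが甘くなること。,
T5B,device,T5CD-04,緩み,,構成部品の固着部 (ねじ、接着等) の結合力が弱まり、正常状態に比べて部品が動いてしまうこと,
T5B,device,T5CD-04,緩み,,接続部分、固定などが緩むこと。,
T5B,device,T5CD-04,緩み,,通電不良となる接続部の固定力不足,
T5B,patient,T5CP-01,感染症,,病原体が生体内に侵入し、一定の病変を惹起すること。,
T5B,patient,T5CP-02,心室細動,,心臓の心室が小刻みに震えて全身に血液を送ることができない状態。,
T5B,patient,T5CP-02,心室細動,,患者の心臓の拍動が小刻みな状態となって、拍出ができない状態。,
T5B,patient,T5CP-03,手術時間の延長,,医療機器の使用にともなう健康被害の発生に関連し、手術時間が長引いてしまうこと。,
T5B,patient,T5CP-04,虹彩脱出,,眼球の穿孔部からの虹彩の一部が眼球外に脱出した状態,
T5B,patient,T5CP-05,感染,,病原微生物が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと。,
T5B,patient,T5CP-05,感染,,微生物が人体に侵入、増殖、何らの症状が出現する症例,
T5B,patient,T5CP-05,感染,,微生物感染などによるもので、キズ口の周りが赤くなっていたり、ズキズキした痛みが続いたり、膿を持っていたり、熱や腫れ等の異常が認められる場合,
T5B,patient,T5CP-05,感染,,微生物が、体内に侵入・定着した状態をいう。,
T6A,device,T6CD-01,ねじれ,,,"Material twisted, kinked"
T6A,device,T6CD-02,アラーム誤作動,,,"Defective alarm, improper alarm, device alarm system issue"
T6A,device,T6CD-03,アラーム音不良,,,"Device alarm system issue, not audible alarm"
T6A,device,故障,変形,,,"""Lens aberration, distortion of"", material distortion, ""Quality, unsatisfactory or poor"", Material deformation, ""component(s), broken"", material deformation, bend, material integrity issue"
T6A,patient,T6CP-01,巨大乳頭結膜炎,,,"Foreign body reaction, hypersensitivity, conjunctivitis"
T6A,patient,T6CP-02,湿疹,,,"Rash, skin inflammation"
T6A,patient,感染,アレルギー反応,,,"Hypersensitivity, allergic reaction"
T6A,patient,T6CP-04,穿孔,,,"""Vessels, perforation of"", cardiac perforation, perforation, injury"
T7A,device,T7CD-01,損傷,,,
T7A,device,T7CD-02,汚染,,,
T7A,device,T7CD-03,発熱,,,
T7A,device,T7CD-04,感染,,,
T7A,device,T7CD-05,感電,,,
T7A,device,T7CD-06,その他の事象,,,
T7A,device,T7CD-07,その他,,,
T7A,device,T7CD-08,不明,,,
T7A,device,T7CD-90,装置固有事象,,,
T7A,device,T7CD-91,装置側事象,共通別名,,
T7B,patient,T7CP-01,損傷,,,
T7B,patient,T7CP-02,汚染,,,
T7B,patient,T7CP-03,発熱,,,
T7B,patient,T7CP-04,感染,,,
T7B,patient,T7CP-05,感電,,,
T7B,patient,T7CP-06,その他の事象,,,
T7B,patient,T7CP-07,その他,,,
T7B,patient,T7CP-08,不明,,,
T7B,patient,T7CP-90,患者固有事象,,,
T7B,patient,T7CP-91,患者側事象,共通別名,,
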